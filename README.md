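# fraxkit

Tools for building and comparing **country-specific FRAX-style
fracture-probability models** from regional hip-fracture registries.

Many countries assess osteoporotic fracture risk with a calculator built on
another country's fracture epidemiology, because no national model exists.
When local incidence data finally become available, three tasks arise:

1. **Ascertain incident hip fractures** from messy multi-source registries
   (ambulance, hospital and outpatient records) — de-duplicating admissions,
   excluding pathological and unspecified-site fractures, and converting
   counts to rates against catchment population;
2. **Build the national model** — smooth the banded rates into a
   continuous-age hazard, combine it with the national death hazard and a
   multiplicative clinical-risk-factor model, and integrate out competing
   mortality to get 10-year and remaining-lifetime fracture probabilities;
3. **Compare the new model with the imported one** over an exhaustive grid
   of clinical scenarios, to quantify how badly the imported model mis-stated
   absolute risk and whether it at least ranked patients correctly.

`fraxkit` implements all three stages as a tested, scriptable pipeline, plus
a synthetic-data module that generates registries with known ground truth so
every stage can be validated end to end.

## The model

Hip-fracture incidence in 5-year age bands is smoothed by piecewise linear
regression of log rates on age with a fixed breakpoint at 67 years and
continuity at the knot:

```
log h(a) = β₀ + β₁ · (min(a, 67) − 40) + β₂ · max(a − 67, 0)
```

The probability of a first fracture between age *a* and horizon *T*, under
competing mortality, is

```
P = ∫₀ᵀ h_f(a+u) · exp( −∫₀ᵘ [h_f(a+v) + h_d(a+v)] dv ) du
```

where `h_f` is the fracture hazard adjusted multiplicatively for the
individual's clinical risk factors and femoral-neck BMD
(`gradient_of_risk^(T-score deficit)`), and `h_d` is the age/sex death
hazard.  The hazard of a major osteoporotic fracture (hip, clinical spine,
forearm, humerus) is imputed from the hip hazard through an age- and
sex-specific ratio table.  Two models are compared over the canonical grid
of all 2⁶ combinations of six risk factors × eight T-scores (0 to −3.5 SD in
0.5 SD steps) = **512 scenarios** per age/sex/outcome, summarised by Pearson
correlation, piecewise regression of one model on the other, and percentile
tables with 95% tolerance intervals.

The true FRAX beta coefficients are proprietary; the engine takes a
configurable risk-model table (`example_risk_config()` ships example values
of published meta-analysis magnitude), so exact replication of FRAX output
is explicitly not claimed.

## Worked example

Run the full demo pipeline (synthetic three-region registry → ascertainment
→ smoothing → model → 512-scenario comparison against a 0.4-scaled contrast
model):

```sh
fraxkit run --out-dir demo_run --seed 1
```

`demo_run/incidence.csv` holds the pooled banded rates, e.g. for women:

```
region    sex  age_low  age_high  n_cases  person_years     rate
pooled female       40      45.0       15       68750.0 0.000218
pooled female       45      50.0       17       56375.0 0.000302
```

and `demo_run/model_a.json` the smoothed hazard — for women: intercept
−8.552 (log rate at age 40), pre-knot slope 0.046/yr, post-knot slope
0.107/yr at the fixed knot 67.  Individual predictions:

```sh
$ fraxkit probability --model demo_run/model_a.json --age 70 --sex F \
      --tscore -2.5 --factors prior_fracture --outcome mof
0.229158
$ fraxkit lifetime --model demo_run/model_a.json --age 50 --sex F --outcome hip
0.084864
```

i.e. a 70-year-old woman with a prior fragility fracture and femoral-neck
T-score −2.5 has a 22.9% 10-year probability of a major osteoporotic
fracture under this synthetic model, and a 50-year-old woman with no risk
factors an 8.5% remaining-lifetime hip-fracture probability.  The comparison
report (`demo_run/report.csv`) shows, for women aged 70 (MOF), Pearson
r = 0.989 between the two models with the scaled model's median probability
lower by 55.5% — the scaled-down model stratifies risk identically while
producing uniformly lower absolute probabilities:

```
age    sex outcome percentile    p_a    p_b  ti_low  ti_high
 70 female     mof         10 0.1226 0.0483  0.0477   0.0557
 70 female     mof         50 0.2924 0.1336  0.1243   0.1361
 70 female     mof         90 0.5930 0.3081  0.2862   0.3265
```

The same stages are available as library functions (`filter_cases`,
`tabulate_incidence`, `amalgamate`, `fit_piecewise_loglinear`,
`probability`, `compare_models`) and as stage-wise commands
(`simulate-registry`, `ascertain`, `fit-incidence`, `build-model`,
`probability`, `lifetime`, `compare`).

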