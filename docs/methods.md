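# Methods

## Case ascertainment

A registry row is one admission or contact (ambulance, hospital or
outpatient).  Inclusion requires an ICD-10 hip site code — S72.0 (femoral
neck), S72.1 (trochanteric), S72.2 (subtrochanteric) — or S72.9 (unspecified
femoral fracture) accompanied by a surgical procedure on the hip; age ≥ 40
at admission; and no neoplasia flag.  Ambulance contacts where the patient
refused hospitalization are retained.  No residence criterion is applied:
non-resident cases enter the numerator while the denominator remains the
catchment population — a deliberate reproduction of common registry practice
and a documented source of upward bias.

**Deduplication.**  One fracture per (patient, site code) within any 365-day
window; the earliest admission is retained.  An excluded later admission is
logged as `duplicate_same_fracture` when the gap is ≤ 90 days (the same
treatment episode) and as `prior_year_same_site` when the retained admission
falls in an earlier calendar year; other within-window repeats are
duplicates.  The 90-day episode bound is a package choice: hip-fracture
treatment and rehabilitation contacts cluster well inside three months,
while a same-site admission several months later that crosses a calendar
year is best read as a previous-year fracture.  Admissions for the same site
more than 365 days apart count as new fractures.

Rule order per record: site code → unspecified-site-without-surgery →
neoplasia → age floor → temporal deduplication.  Every dropped record gets
exactly one reason; `included + excluded = input` always.  The age floor is
configurable per run (some regional studies enrol from 50); the default is
40, the lower bound of the probability model.

**Rates.**  Incidence per (sex, 5-year band) is cases divided by
person-years (= catchment population × observation-window length).  Bands
are half-open `[lo, lo+5)` from 40 with an open 95+ top band.  The
observation-window length is an explicit input, not inferred, because
multi-year registries with a single denominator year are common and any
implicit reconciliation would be a guess.  Regional tables are amalgamated
by catchment-population weighting, `Σ(rate_r·pop_r)/Σ pop_r`, which for
equal-length windows is algebraically identical to pooling raw numerators
and denominators (tested to 1e-12).

## Incidence smoothing

Log rates at band midpoints (42.5 for `[40,45)`, …, lower-edge + 2.5 for the
open top band) are fitted by least squares with a hinge at the fixed knot of
67 years, enforcing continuity: one intercept (log rate at the reference age
40) and two slopes per sex.  The knot is configuration, not estimated;
weighting by case counts is available but off by default.  Zero-rate bands
are dropped from the log-scale fit with a warning.  Fewer than three
positive-rate bands, or no positive band on one side of the knot, is an
error.  Noiseless band rates generated from a two-segment model are
recovered to ≈ 1e-15.

Sampling precision: with band-level Poisson noise the pre-knot slope is the
binding parameter.  Its standard error is roughly `1/√n_band` (log-rate SD)
divided by the age spread of the pre-knot bands (≈ 15.8 years of root
sum-of-squares), so ~200 cases/band gives SE ≈ 0.0045 — too coarse to pin a
slope of 0.05/yr to 5%.  The recovery tests therefore use ≈ 5,000 expected
cases per band (SE ≈ 0.0009), the precision a pooled multi-region,
multi-year registry would supply.

## Probability engine

The first-fracture probability from start age *a* over horizon *T* under
competing mortality is the standard double integral (README).  Numerics:
both hazards are treated as constant on a uniform sub-year grid and the
exact constant-hazard competing-risk solution
`h_f/(h_f+h_d)·(1−exp(−(h_f+h_d)Δt))` is accumulated with the running joint
survival.  Constant hazards are therefore reproduced to floating-point
precision, and smooth hazards converge at second order.  The default step is
**0.005 years**, at which halving the step changes a probability by < 1e-8
for the steepest realistic (log-linear, slope ≈ 0.11/yr) hazards; a larger
step would be faster but breaks that convergence guarantee.  Tabulated death
hazards (single years of age, 40–110) are interpolated log-linearly between
entries.  Ten-year outputs are served for start ages 40–90; lifetime outputs
integrate to a maximum age of 110.

**Risk factors.**  Seven dichotomous factors act multiplicatively through
configured relative risks per outcome; femoral-neck BMD contributes
`gradient_of_risk^(reference_tscore − tscore)`; BMI contributes
`rr_per_bmi_unit^(25 − bmi)` and defaults to neutral (RR 1/unit) because the
canonical comparison fixes BMI at 25 kg/m².  When BMD is entered, secondary
osteoporosis contributes no multiplier (configurable): its risk is assumed
to act through BMD.  No recalibration of the baseline hazard for risk-factor
prevalence is performed — the baseline represents a person with no risk
factors rather than an average-risk person; a production calculator
calibrated to population-average risk would rescale the baseline, and the
configuration is the hook for doing so.

**MOF imputation.**  Major-osteoporotic-fracture hazard = hip hazard × an
age/sex ratio, read from a (sex, age, ratio) table at the nearest tabulated
age.  The packaged table in `example_risk_config()` is a **synthetic
example** (declining from ~7× at 50 to ~1.7× at 95 in women, 5→2 in men,
the conventional shape); users building a real model must substitute
literature ratios, which are not bundled here.

## Synthetic data

The generator emulates the structure of a multi-source registry year: case
counts per (region, sex, band) are Poisson with mean rate(midpoint) ×
population, ages uniform within the band, admission dates uniform over the
year.  Plants: exact duplicate re-admissions 1–60 days later; extra
neoplasia-flagged rows; extra S72.9 rows (a sub-fraction with hip surgery,
which are genuine cases and counted in the truth); prior-year same-site
admissions 91–364 days earlier across a calendar-year boundary; and
ambulance-refusal flags on retained cases.  Every plant except
S72.9-with-surgery is an extra row, so emitted rows = true cases + planted
exclusions exactly, and the filter must return exactly the true cases.
Defaults (three regions of 25–60 k per sex-band pyramid declining 18% per
band; duplicates 8%, neoplasia 3%, S72.9 5% with 30% operated, prior-year
2%, refusals 5%; Gompertz mortality α = 1.6e-5/3.5e-5 per year for
women/men, β = 0.095/yr) are one fixed realistic choice, not tuned.  What
the generator does **not** emulate: seasonality, urban/rural gradients,
secular trends, misspelled identifiers, and age misstatement — so passing
tests demonstrate correctness of the pipeline's logic, not robustness to
those real-data pathologies.

## Model comparison

Scenario grids enumerate all 2^k factor combinations × m T-score levels
(deterministic order: T-score outermost, factors as a binary counter); the
canonical grid is k = 6, m = 8 → 512.  Secondary osteoporosis is omitted
from the six grid factors because BMD is entered in every scenario, making
it inert under the default configuration.  All scenarios share one baseline
hazard, so a grid is evaluated as a single (scenarios × steps) array.

The relation of model B to model A is summarised by a continuous
piecewise-linear least-squares regression of p_B on p_A with fixed hinges —
defaults 50% and 70% (MOF) and 5% and 20% (hip), reflecting the different
probability ranges of the two outcomes; knots outside the observed range are
dropped with a warning.  Percentile rows (10/50/90, linear interpolation
between order statistics) report the model-A value, the regression fit as
the model-B central estimate, and a 95% interval.

**Tolerance intervals.**  The default interval is the empirical 2.5–97.5
percentile range of model-B probabilities among scenarios whose model-A
percentile rank lies within ±2 ranks of the target percentile (~20 of 512
scenarios).  This is a nonparametric, reproducible construction — an
interpretation, since tolerance intervals for such tables are rarely defined
precisely in print.  An OLS 95% prediction interval over the same piecewise
design is available via `interval="prediction"`.  When all model-A values
are tied the whole tied mass is the neighbourhood, giving the expected
zero-width interval for degenerate inputs.

Known limitation: the central estimate is a *global* piecewise fit while the
band is *local*, so in cells where the fixed knots sit outside or near the
edge of the observed range (e.g. hip knots of 5/20% applied at ages where
probabilities concentrate above 20%) the fit can fall outside the band at
the 10th-percentile tail.  The band itself retains ≥ 90% coverage of its
neighbourhood by construction; when the regression is well specified the
central estimate lies inside the band.

`summarize` reports Pearson r of the paired probabilities and the signed
median of (p_A − p_B)/p_A as a percentage.  Because risk multipliers are
products of a small set of relative risks, distinct scenarios can tie
*exactly* (e.g. one factor RR equal to one SD of the BMD gradient); rank
order between two models is therefore asserted over strictly ordered pairs,
ties being rank-ambiguous by construction.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy `default_rng`);
fixed seed ⇒ byte-identical registries and bit-identical pipeline outputs
(verified via manifest hashes).  The bundled demo and the acceptance script
use a three-region registry of roughly 800–1,000 rows, 200 Poisson-noise
fit replicates, 100 random amalgamation configurations and four 512-scenario
comparison grids — sizes chosen so a full run completes in seconds while
keeping every estimate's sampling error far below the margins being tested.
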