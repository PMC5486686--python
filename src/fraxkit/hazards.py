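"""Fracture-probability engine with competing mortality.

Combines a smoothed hip-fracture hazard, an age/sex death hazard and a
multiplicative clinical-risk-factor model into 10-year and remaining-lifetime
probabilities of hip fracture and major osteoporotic fracture (MOF: hip,
clinical spine, distal forearm, proximal humerus).

The probability of a first fracture between the start age ``a`` and horizon
``T`` under competing mortality is

    P = int_0^T  h_f(a+u) * exp( -int_0^u [h_f(a+v) + h_d(a+v)] dv ) du

where ``h_f`` is the (risk-factor-adjusted) fracture hazard and ``h_d`` the
death hazard, both per person-year.  The integral is evaluated by treating
both hazards as constant on a fine age grid (default step 0.005 years) and
accumulating the exact within-step competing-risk solution, so constant
hazards are reproduced to floating-point accuracy and smooth hazards
converge at second order in the step.

Because MOF incidence is rarely observable from hip-fracture registries, the
MOF hazard is imputed as the hip hazard times an age/sex-specific ratio
(assumed transportable from a well-characterised reference population, as is
conventional for this model family).

Risk factors act multiplicatively: each present dichotomous factor
contributes its relative risk; femoral-neck BMD contributes
``gradient_of_risk ** (reference_tscore - tscore)`` per SD below the
reference; BMI contributes ``rr_per_bmi_unit ** (25 - bmi)`` around the
neutral point 25 kg/m².  Exact replication of the proprietary FRAX beta
coefficients is not claimed: the engine takes a configurable risk-model
table, and the packaged example uses published meta-analysis magnitudes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .incidence import PiecewiseLogLinearModel, AGE_RANGE

__all__ = [
    "CLINICAL_RISK_FACTORS",
    "RiskFactorProfile",
    "RiskModelConfig",
    "CountryModel",
    "hazard_table",
    "death_hazard_fn",
    "mof_hazard",
    "risk_multiplier",
    "adjusted_hazard",
    "ten_year_probability",
    "lifetime_probability",
    "probability",
    "example_risk_config",
    "DEFAULT_STEP_YEARS",
    "MAX_AGE",
    "TEN_YEAR_AGE_RANGE",
]

#: The seven dichotomous clinical risk factors.
CLINICAL_RISK_FACTORS = (
    "prior_fracture",
    "parental_hip_fracture",
    "current_smoking",
    "glucocorticoids",
    "rheumatoid_arthritis",
    "secondary_osteoporosis",
    "alcohol_excess",
)

OUTCOMES = ("hip", "mof")
#: Default quadrature step in years; see module docstring.
DEFAULT_STEP_YEARS = 0.005
MAX_AGE = 110.0
#: Operational start-age range for 10-year outputs.
TEN_YEAR_AGE_RANGE = (40.0, 90.0)
BMI_NEUTRAL = 25.0


@dataclass(frozen=True)
class RiskFactorProfile:
    """One individual's inputs to the probability calculation."""

    age: float
    sex: str
    bmi: float = BMI_NEUTRAL
    tscore: float | None = None
    prior_fracture: bool = False
    parental_hip_fracture: bool = False
    current_smoking: bool = False
    glucocorticoids: bool = False
    rheumatoid_arthritis: bool = False
    secondary_osteoporosis: bool = False
    alcohol_excess: bool = False

    def __post_init__(self) -> None:
        if self.bmi <= 0:
            raise ValueError("bmi must be positive")
        if not AGE_RANGE[0] <= self.age <= AGE_RANGE[1]:
            raise ValueError(f"age {self.age} outside supported range {AGE_RANGE}")

    def factors_present(self) -> tuple[str, ...]:
        return tuple(f for f in CLINICAL_RISK_FACTORS if getattr(self, f))

    def with_factors(self, **flags: bool) -> "RiskFactorProfile":
        d = asdict(self)
        d.update(flags)
        return RiskFactorProfile(**d)


def _per_outcome(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {o: float(value[o]) for o in OUTCOMES}
    return {o: float(value) for o in OUTCOMES}


@dataclass
class RiskModelConfig:
    """Multiplicative risk-model table.

    ``relative_risks`` maps each clinical risk factor to its relative risk,
    either one number for both outcomes or ``{"hip": ..., "mof": ...}``.
    ``gradient_of_risk`` is the relative risk per SD decrease in
    femoral-neck T-score, likewise per outcome.  ``hip_to_mof_ratio`` is a
    table (sex, age, ratio) giving the multiplier from hip hazard to MOF
    hazard; the nearest tabulated age is used between entries.
    """

    relative_risks: dict = field(default_factory=dict)
    gradient_of_risk: dict | float = 1.6
    reference_tscore: float = 0.0
    rr_per_bmi_unit: float = 1.0
    secondary_osteoporosis_inactive_with_bmd: bool = True
    hip_to_mof_ratio: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.relative_risks = {
            k: _per_outcome(v) for k, v in self.relative_risks.items()
        }
        unknown = set(self.relative_risks) - set(CLINICAL_RISK_FACTORS)
        if unknown:
            raise ValueError(f"unknown risk factors in config: {sorted(unknown)}")
        for k, per in self.relative_risks.items():
            if any(rr <= 0 for rr in per.values()):
                raise ValueError(f"relative risk for {k!r} must be positive")
        self.gradient_of_risk = _per_outcome(self.gradient_of_risk)
        if any(g <= 0 for g in self.gradient_of_risk.values()):
            raise ValueError("gradient_of_risk must be positive")
        if self.rr_per_bmi_unit <= 0:
            raise ValueError("rr_per_bmi_unit must be positive")

    def rr(self, factor: str, outcome: str) -> float:
        per = self.relative_risks.get(factor)
        return 1.0 if per is None else per[outcome]

    def ratio_fn(self, sex: str) -> Callable:
        """Vectorized hip→MOF multiplier using the nearest tabulated age."""
        if self.hip_to_mof_ratio is None:
            raise ValueError("no hip:MOF ratio table configured")
        sub = self.hip_to_mof_ratio[self.hip_to_mof_ratio["sex"] == sex]
        if sub.empty:
            raise ValueError(f"no hip:MOF ratios for sex {sex!r}")
        ages = sub["age"].to_numpy(dtype=float)
        ratios = sub["ratio"].to_numpy(dtype=float)
        order = np.argsort(ages)
        ages, ratios = ages[order], ratios[order]
        boundaries = (ages[1:] + ages[:-1]) / 2.0

        def f(age):
            idx = np.searchsorted(boundaries, np.asarray(age, dtype=float))
            return ratios[idx]

        return f

    def ratio(self, sex: str, age: float) -> float:
        """Hip→MOF multiplier at the nearest tabulated age."""
        return float(self.ratio_fn(sex)(age))

    def to_dict(self) -> dict:
        return {
            "relative_risks": self.relative_risks,
            "gradient_of_risk": self.gradient_of_risk,
            "reference_tscore": self.reference_tscore,
            "rr_per_bmi_unit": self.rr_per_bmi_unit,
            "secondary_osteoporosis_inactive_with_bmd": self.secondary_osteoporosis_inactive_with_bmd,
            "hip_to_mof_ratio": (
                None
                if self.hip_to_mof_ratio is None
                else self.hip_to_mof_ratio.to_dict(orient="list")
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModelConfig":
        d = dict(d)
        ratio = d.pop("hip_to_mof_ratio", None)
        if ratio is not None:
            ratio = pd.DataFrame(ratio)
        return cls(hip_to_mof_ratio=ratio, **d)


def hazard_table(sexes, ages, hazards) -> pd.DataFrame:
    """Assemble and validate a death-hazard table (sex, age, hazard)."""
    df = pd.DataFrame({"sex": sexes, "age": ages, "hazard": hazards})
    if (df["hazard"] < 0).any():
        raise ValueError("death hazards must be non-negative")
    return df


def death_hazard_fn(table: pd.DataFrame, sex: str) -> Callable:
    """Death hazard as a function of age, log-linearly interpolated
    between tabulated single years of age."""
    sub = table[table["sex"] == sex].sort_values("age")
    if sub.empty:
        raise ValueError(f"death-hazard table has no rows for sex {sex!r}")
    ages = sub["age"].to_numpy(dtype=float)
    log_h = np.log(np.maximum(sub["hazard"].to_numpy(dtype=float), 1e-300))

    def h_d(age):
        arr = np.asarray(age, dtype=float)
        if np.any(arr < ages[0]) or np.any(arr > ages[-1]):
            raise ValueError(
                f"death hazard undefined outside [{ages[0]}, {ages[-1]}]"
            )
        return np.exp(np.interp(arr, ages, log_h))

    return h_d


@dataclass
class CountryModel:
    """A deployable FRAX-style model: per-sex hip hazard, death hazard and
    risk-model configuration."""

    hip: dict[str, PiecewiseLogLinearModel]
    death: pd.DataFrame
    risk: RiskModelConfig

    def hip_hazard(self, sex: str) -> Callable:
        if sex not in self.hip:
            raise ValueError(f"no hip-hazard model for sex {sex!r}")
        return self.hip[sex].rate

    def death_hazard(self, sex: str) -> Callable:
        return death_hazard_fn(self.death, sex)

    def scaled_hip(self, factor: float) -> "CountryModel":
        """New model with every hip hazard multiplied by ``factor``; death
        hazard and risk configuration unchanged."""
        return CountryModel(
            hip={s: m.scaled(factor) for s, m in self.hip.items()},
            death=self.death,
            risk=self.risk,
        )

    def to_dict(self) -> dict:
        return {
            "hip": {s: m.to_dict() for s, m in self.hip.items()},
            "death": self.death.to_dict(orient="list"),
            "risk": self.risk.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CountryModel":
        return cls(
            hip={
                s: PiecewiseLogLinearModel.from_dict(m) for s, m in d["hip"].items()
            },
            death=pd.DataFrame(d["death"]),
            risk=RiskModelConfig.from_dict(d["risk"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CountryModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def mof_hazard(model: CountryModel, sex: str, age):
    """MOF hazard imputed as hip hazard × configured hip:MOF ratio."""
    hip = model.hip_hazard(sex)
    ratio = model.risk.ratio_fn(sex)
    arr = np.asarray(age, dtype=float)
    out = np.asarray(hip(arr), dtype=float) * ratio(arr)
    return float(out) if arr.ndim == 0 else out


def risk_multiplier(
    profile: RiskFactorProfile, config: RiskModelConfig, outcome: str
) -> float:
    """Product of the relative risks implied by a profile for one outcome."""
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    mult = 1.0
    for factor in profile.factors_present():
        if (
            factor == "secondary_osteoporosis"
            and profile.tscore is not None
            and config.secondary_osteoporosis_inactive_with_bmd
        ):
            continue
        mult *= config.rr(factor, outcome)
    if profile.tscore is not None:
        g = config.gradient_of_risk[outcome]
        mult *= g ** (config.reference_tscore - profile.tscore)
    mult *= config.rr_per_bmi_unit ** (BMI_NEUTRAL - profile.bmi)
    return mult


def adjusted_hazard(
    baseline: Callable, profile: RiskFactorProfile, config: RiskModelConfig,
    outcome: str = "hip",
) -> Callable:
    """Baseline hazard with the profile's multiplier applied pointwise."""
    mult = risk_multiplier(profile, config, outcome)

    def h(age):
        return mult * np.asarray(baseline(age), dtype=float)

    return h


def _integrate_competing(hf: np.ndarray, hd: np.ndarray, dt: float):
    """Cumulative first-event probability for piecewise-constant hazards.

    ``hf`` may be (n,) or (m, n) for m hazard curves sharing one death
    hazard; the within-step solution h_f/(h_f+h_d) * (1 - exp(-h_tot dt)) is
    exact for constant hazards.
    """
    htot = hf + hd
    step_surv = np.exp(-htot * dt)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(htot > 0, hf / np.where(htot > 0, htot, 1.0), 0.0)
    p_step = frac * (1.0 - step_surv)
    surv = np.cumprod(step_surv, axis=-1)
    surv_before = np.concatenate(
        [np.ones(surv.shape[:-1] + (1,)), surv[..., :-1]], axis=-1
    )
    return np.sum(surv_before * p_step, axis=-1)


def _horizon_probability(
    h_frac: Callable, h_death: Callable, start_age: float, horizon: float,
    step: float,
) -> float:
    n = max(1, int(round(horizon / step)))
    dt = horizon / n
    mid = start_age + (np.arange(n) + 0.5) * dt
    hf = np.asarray(h_frac(mid), dtype=float)
    hd = np.asarray(h_death(mid), dtype=float)
    hf = np.broadcast_to(hf, mid.shape).astype(float)
    hd = np.broadcast_to(hd, mid.shape).astype(float)
    if np.any(hf < 0) or np.any(hd < 0):
        raise ValueError("hazards must be non-negative")
    return float(_integrate_competing(hf, hd, dt))


def ten_year_probability(
    h_frac: Callable, h_death: Callable, start_age: float,
    step: float = DEFAULT_STEP_YEARS,
) -> float:
    """10-year probability of a first fracture under competing mortality."""
    return _horizon_probability(h_frac, h_death, start_age, 10.0, step)


def lifetime_probability(
    h_frac: Callable, h_death: Callable, start_age: float,
    max_age: float = MAX_AGE, step: float = DEFAULT_STEP_YEARS,
) -> float:
    """Remaining lifetime probability of a first fracture from ``start_age``."""
    if max_age <= start_age:
        raise ValueError("max_age must exceed start_age")
    return _horizon_probability(
        h_frac, h_death, start_age, max_age - start_age, step
    )


def probability(
    model: CountryModel,
    profile: RiskFactorProfile,
    outcome: str = "mof",
    horizon: str = "ten_year",
    step: float = DEFAULT_STEP_YEARS,
) -> float:
    """Fracture probability for one profile under one model.

    ``outcome`` is ``"hip"`` or ``"mof"``; ``horizon`` is ``"ten_year"`` or
    ``"lifetime"``.  Ten-year outputs are restricted to start ages 40-90.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}")
    sex = profile.sex
    hip = model.hip_hazard(sex)
    if outcome == "hip":
        base = hip
    else:
        ratio = model.risk.ratio_fn(sex)

        def base(age):
            arr = np.asarray(age, dtype=float)
            return np.asarray(hip(arr), dtype=float) * ratio(arr)

    h = adjusted_hazard(base, profile, model.risk, outcome)
    h_d = model.death_hazard(sex)
    if horizon == "ten_year":
        lo, hi = TEN_YEAR_AGE_RANGE
        if not lo <= profile.age <= hi:
            raise ValueError(
                f"10-year outputs are supported for start ages {lo:.0f}-{hi:.0f}"
            )
        return ten_year_probability(h, h_d, profile.age, step)
    if horizon == "lifetime":
        return lifetime_probability(h, h_d, profile.age, step=step)
    raise ValueError("horizon must be 'ten_year' or 'lifetime'")


def example_risk_config() -> RiskModelConfig:
    """Example risk-model configuration.

    Relative risks and gradients of risk are example values of the
    magnitude reported in published meta-analyses of the clinical risk
    factors; the hip:MOF ratio table is a synthetic example with the
    conventional shape (large at younger ages, approaching ~1.5 in extreme
    old age, higher in women).  Users fitting a real national model must
    supply literature values.
    """
    ratio_rows = []
    for sex, start, end in (("female", 7.0, 1.7), ("male", 5.0, 2.0)):
        for i, age in enumerate(range(50, 100, 5)):
            frac = i / 9.0
            ratio_rows.append(
                {"sex": sex, "age": age, "ratio": start * (end / start) ** frac}
            )
    return RiskModelConfig(
        relative_risks={
            "prior_fracture": {"hip": 1.85, "mof": 1.75},
            "parental_hip_fracture": {"hip": 2.3, "mof": 1.55},
            "current_smoking": {"hip": 1.6, "mof": 1.25},
            "glucocorticoids": {"hip": 2.1, "mof": 1.6},
            "rheumatoid_arthritis": {"hip": 1.7, "mof": 1.45},
            "secondary_osteoporosis": {"hip": 1.65, "mof": 1.35},
            "alcohol_excess": {"hip": 1.7, "mof": 1.4},
        },
        gradient_of_risk={"hip": 2.6, "mof": 1.6},
        reference_tscore=0.0,
        rr_per_bmi_unit=1.0,
        secondary_osteoporosis_inactive_with_bmd=True,
        hip_to_mof_ratio=pd.DataFrame(ratio_rows),
    )
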