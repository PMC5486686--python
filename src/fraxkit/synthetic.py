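"""Synthetic registries, population tables and mortality tables.

Real hip-fracture registries assembled from ambulance, hospital and
outpatient sources are messy in specific, well-understood ways: the same
fracture appears under multiple admissions, pathological fractures from
neoplasia are present, some femoral fractures carry the unspecified-site
code S72.9, patients re-present for fractures sustained in the previous
year, and some ambulance contacts refuse hospitalization.  This module
generates registries with exactly that structure planted on top of a known
piecewise log-linear incidence, together with the matching catchment
population and a Gompertz death-hazard table, so that every downstream stage
(filtering, tabulation, amalgamation, smoothing, probability) can be tested
against ground truth.

Design: case counts per (region, sex, 5-year band) are Poisson with mean
rate(band midpoint) × population; ages are uniform within the band; a single
simulation year per registry (multi-year studies are concatenated years).
All plants except S72.9-with-surgery are extra rows over the true cases, so
the emitted row count always equals true cases plus planted exclusions.
S72.9 rows whose surgical flag indicates hip surgery are genuine cases and
are counted in the truth.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ascertainment import (
    AGE_BAND_EDGES,
    CaseRecord,
    TOP_BAND_LOW,
    band_label,
)
from .hazards import CountryModel, hazard_table
from .incidence import PiecewiseLogLinearModel

__all__ = [
    "RegistrySimConfig",
    "SimTruth",
    "generate_registry",
    "generate_population",
    "generate_mortality",
    "generate_reference_model",
    "uniform_population",
    "default_sim_config",
    "default_true_incidence",
]

_HIP_CODES = ("S72.0", "S72.1", "S72.2")
_HIP_CODE_P = (0.5, 0.4, 0.1)


@dataclass
class RegistrySimConfig:
    """Ground-truth configuration for one simulated registry year."""

    regions: list[str]
    population_per_band: dict[tuple[str, str, int], int]
    true_incidence: dict[str, PiecewiseLogLinearModel]
    planted_duplicate_fraction: float = 0.0
    planted_neoplasia_fraction: float = 0.0
    planted_s729_fraction: float = 0.0
    s729_surgery_fraction: float = 0.3
    planted_prioryear_fraction: float = 0.0
    refused_hospitalization_fraction: float = 0.0
    year: int = 2012
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "planted_duplicate_fraction": self.planted_duplicate_fraction,
            "planted_neoplasia_fraction": self.planted_neoplasia_fraction,
            "planted_s729_fraction": self.planted_s729_fraction,
            "s729_surgery_fraction": self.s729_surgery_fraction,
            "planted_prioryear_fraction": self.planted_prioryear_fraction,
            "refused_hospitalization_fraction": self.refused_hospitalization_fraction,
        }
        for name, f in fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {f}")
        # duplicate and prior-year plants attach to distinct true cases
        if self.planted_duplicate_fraction + self.planted_prioryear_fraction > 1.0:
            raise ValueError(
                "duplicate and prior-year fractions are mutually exclusive "
                "plants and must sum to at most 1"
            )
        if not self.regions:
            raise ValueError("need at least one region")
        for (region, sex, band_low), count in self.population_per_band.items():
            if count <= 0:
                raise ValueError(
                    f"population must be strictly positive; band "
                    f"{band_label(band_low)} ({sex}, {region!r}) has {count}"
                )
        missing = set(self.true_incidence) ^ {s for (_, s, _) in self.population_per_band}
        if missing:
            raise ValueError(f"incidence/population sex mismatch: {sorted(missing)}")


@dataclass
class SimTruth:
    """What was actually planted; reconciles with the emitted registry."""

    n_true_cases: dict[tuple[str, str, int], int] = field(default_factory=dict)
    n_planted_exclusions: dict[str, int] = field(default_factory=dict)
    total_rows: int = 0

    @property
    def n_true_total(self) -> int:
        return sum(self.n_true_cases.values())

    def to_json(self, path) -> None:
        payload = {
            "n_true_cases": {
                f"{r}|{s}|{b}": n for (r, s, b), n in self.n_true_cases.items()
            },
            "n_planted_exclusions": self.n_planted_exclusions,
            "total_rows": self.total_rows,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _band_keys(config: RegistrySimConfig):
    return sorted(config.population_per_band.keys())


def _random_date(rng: np.random.Generator, year: int) -> _dt.date:
    return _dt.date(year, 1, 1) + _dt.timedelta(days=int(rng.integers(0, 365)))


def generate_registry(
    config: RegistrySimConfig,
) -> tuple[list[CaseRecord], SimTruth]:
    """Emit one simulated registry year plus its ground truth.

    Deterministic for a fixed seed: the same configuration reproduces the
    registry byte for byte.
    """
    rng = np.random.default_rng(config.seed)
    truth = SimTruth(
        n_planted_exclusions={
            "duplicate_same_fracture": 0,
            "neoplasia": 0,
            "s729_no_surgery": 0,
            "prior_year_same_site": 0,
        }
    )
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:06d}"

    true_cases: list[CaseRecord] = []
    for region, sex, band_low in _band_keys(config):
        pop = config.population_per_band[(region, sex, band_low)]
        model = config.true_incidence[sex]
        mid = band_low + 2.5
        lam = model.rate(mid) * pop
        n = int(rng.poisson(lam))
        truth.n_true_cases[(region, sex, band_low)] = n
        hi = 105 if band_low >= TOP_BAND_LOW else band_low + 5
        for _ in range(n):
            true_cases.append(
                CaseRecord(
                    patient_id=new_id(),
                    region=region,
                    sex=sex,
                    age_years=int(rng.integers(band_low, hi)),
                    admission_date=_random_date(rng, config.year),
                    icd10_code=_HIP_CODES[
                        int(rng.choice(len(_HIP_CODES), p=_HIP_CODE_P))
                    ],
                    source="hospital",
                )
            )

    n_true = len(true_cases)
    n_dup = round(config.planted_duplicate_fraction * n_true)
    n_prior = round(config.planted_prioryear_fraction * n_true)
    n_neo = round(config.planted_neoplasia_fraction * n_true)
    n_s729 = round(config.planted_s729_fraction * n_true)
    n_s729_surg = round(config.s729_surgery_fraction * n_s729)
    n_refused = round(config.refused_hospitalization_fraction * n_true)

    # refusals: retained cases that only touched the ambulance service
    if n_refused:
        for i in rng.permutation(n_true)[:n_refused]:
            true_cases[i] = dataclasses.replace(
                true_cases[i], refused_hospitalization=True, source="ambulance"
            )

    perm = rng.permutation(n_true)
    dup_idx = perm[:n_dup]
    prior_idx = perm[n_dup : n_dup + n_prior]

    extra: list[CaseRecord] = []
    for i in dup_idx:
        rec = true_cases[i]
        gap = int(rng.integers(1, 61))
        extra.append(
            dataclasses.replace(
                rec,
                admission_date=rec.admission_date + _dt.timedelta(days=gap),
                refused_hospitalization=False,
                source="hospital",
            )
        )
        truth.n_planted_exclusions["duplicate_same_fracture"] += 1

    for i in prior_idx:
        rec = true_cases[i]
        yday = rec.admission_date.timetuple().tm_yday
        if yday > 360:  # keep the prior-year gap under 365 days
            rec = dataclasses.replace(
                rec, admission_date=rec.admission_date - _dt.timedelta(days=7)
            )
            true_cases[i] = rec
            yday -= 7
        gap = int(rng.integers(max(yday, 91), 365))
        extra.append(
            dataclasses.replace(
                rec,
                admission_date=rec.admission_date - _dt.timedelta(days=gap),
                refused_hospitalization=False,
                source="hospital",
            )
        )
        truth.n_planted_exclusions["prior_year_same_site"] += 1

    def template(i: int) -> CaseRecord:
        return true_cases[int(i)] if n_true else None

    for _ in range(n_neo):
        t = template(rng.integers(0, n_true)) if n_true else None
        extra.append(
            CaseRecord(
                patient_id=new_id(),
                region=t.region if t else config.regions[0],
                sex=t.sex if t else "female",
                age_years=t.age_years if t else 70,
                admission_date=_random_date(rng, config.year),
                icd10_code=_HIP_CODES[
                    int(rng.choice(len(_HIP_CODES), p=_HIP_CODE_P))
                ],
                neoplasia=True,
                source="hospital",
            )
        )
        truth.n_planted_exclusions["neoplasia"] += 1

    for j in range(n_s729):
        t = template(rng.integers(0, n_true)) if n_true else None
        surgery = j < n_s729_surg
        rec = CaseRecord(
            patient_id=new_id(),
            region=t.region if t else config.regions[0],
            sex=t.sex if t else "female",
            age_years=t.age_years if t else 70,
            admission_date=_random_date(rng, config.year),
            icd10_code="S72.9",
            hip_surgery=surgery,
            source="hospital",
        )
        extra.append(rec)
        if surgery:  # a genuine hip fracture the filter retains
            key = (
                rec.region,
                rec.sex,
                min(TOP_BAND_LOW, 40 + 5 * ((rec.age_years - 40) // 5)),
            )
            truth.n_true_cases[key] = truth.n_true_cases.get(key, 0) + 1
        else:
            truth.n_planted_exclusions["s729_no_surgery"] += 1

    records = true_cases + extra
    records.sort(
        key=lambda r: (r.admission_date, r.patient_id, r.icd10_code, r.region)
    )
    truth.total_rows = len(records)
    return records, truth


def generate_population(config: RegistrySimConfig) -> pd.DataFrame:
    """Catchment population table: one row per (region, sex, 5-year band)."""
    rows = []
    for region, sex, band_low in _band_keys(config):
        rows.append(
            {
                "region": region,
                "sex": sex,
                "age_low": band_low,
                "age_high": np.inf if band_low >= TOP_BAND_LOW else band_low + 5,
                "person_count": config.population_per_band[(region, sex, band_low)],
                "year": config.year,
            }
        )
    return pd.DataFrame(rows)


def generate_mortality(alpha, beta, sexes=("female", "male")) -> pd.DataFrame:
    """Gompertz death-hazard table h_d(a) = alpha * exp(beta * a).

    ``alpha`` (rate/year) and ``beta`` (1/year) may be scalars or mappings
    keyed by sex; the table covers single years of age 40-110 per sex.
    """
    rows_sex, rows_age, rows_h = [], [], []
    for sex in sexes:
        a = float(alpha[sex]) if isinstance(alpha, dict) else float(alpha)
        b = float(beta[sex]) if isinstance(beta, dict) else float(beta)
        if a <= 0:
            raise ValueError("alpha must be positive")
        if b < 0:
            raise ValueError("beta must be non-negative")
        ages = np.arange(40, 111)
        rows_sex.extend([sex] * len(ages))
        rows_age.extend(ages.tolist())
        rows_h.extend((a * np.exp(b * ages)).tolist())
    return hazard_table(rows_sex, rows_age, rows_h)


def generate_reference_model(base: CountryModel, incidence_scale: float) -> CountryModel:
    """A contrast model: hip hazard scaled by ``incidence_scale`` at every
    age, death hazard and risk configuration unchanged.

    Scaling down emulates comparing a high-incidence imported model against
    a lower-incidence country-specific one.
    """
    if incidence_scale <= 0:
        raise ValueError("incidence_scale must be positive")
    return base.scaled_hip(incidence_scale)


def default_true_incidence() -> dict[str, PiecewiseLogLinearModel]:
    """Plausible Eastern-European-style hip-fracture hazard: male incidence
    higher below ~65, female incidence rising faster after the knot."""
    return {
        "female": PiecewiseLogLinearModel(
            sex="female", intercept=float(np.log(2.0e-4)),
            slope_pre=0.040, slope_post=0.110,
        ),
        "male": PiecewiseLogLinearModel(
            sex="male", intercept=float(np.log(3.0e-4)),
            slope_pre=0.030, slope_post=0.080,
        ),
    }


def uniform_population(
    regions, count: int = 20_000, sexes=("female", "male")
) -> dict[tuple[str, str, int], int]:
    """Equal person counts in every (region, sex, band); a convenience for
    tests and demos."""
    return {
        (r, s, b): count for r in regions for s in sexes for b in AGE_BAND_EDGES
    }


def default_sim_config(seed: int = 0, **overrides) -> RegistrySimConfig:
    """Three-region demo registry with age-declining catchment populations
    and modest planted contamination."""
    regions = ["region_a", "region_b", "region_c"]
    sizes = {"region_a": 60_000, "region_b": 25_000, "region_c": 40_000}
    pop: dict[tuple[str, str, int], int] = {}
    for r in regions:
        for s in ("female", "male"):
            for i, b in enumerate(AGE_BAND_EDGES):
                decline = 0.82**i
                sex_frac = 0.55 if s == "female" else 0.45
                pop[(r, s, b)] = max(1, int(sizes[r] * sex_frac * decline))
    defaults = dict(
        regions=regions,
        population_per_band=pop,
        true_incidence=default_true_incidence(),
        planted_duplicate_fraction=0.08,
        planted_neoplasia_fraction=0.03,
        planted_s729_fraction=0.05,
        s729_surgery_fraction=0.3,
        planted_prioryear_fraction=0.02,
        refused_hospitalization_fraction=0.05,
        year=2012,
        seed=seed,
    )
    defaults.update(overrides)
    return RegistrySimConfig(**defaults)
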