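"""Hip-fracture case ascertainment from multi-source registries.

Registries assembled from ambulance, hospital and outpatient records contain
double-counted admissions, pathological (neoplasia-associated) fractures,
unspecified-site femoral fracture codes and re-admissions for fractures
sustained in a previous year.  This module applies the inclusion and
exclusion rules used when building country-specific fracture-probability
models, tabulates incidence per 5-year age band and sex against catchment
population, and amalgamates regional tables weighted by catchment size.

Inclusion rules
---------------
* ICD-10 site codes S72.0 (femoral neck), S72.1 (trochanter),
  S72.2 (subtrochanter); S72.9 (unspecified femoral fracture) only when a
  surgical procedure indicates surgery on the hip.
* Age 40 years or more at admission (the lower age limit of FRAX-style
  models).
* Neoplasia-associated fractures are excluded.
* One fracture per patient and site: the earliest admission within any
  365-day window is retained; later same-site admissions are excluded as
  duplicates (same treatment episode, gap <= 90 days) or as a prior-year
  fracture at the same site (first admission in an earlier calendar year).
* Ambulance contacts where the patient refused hospitalization are retained.
* No residence-based exclusion: non-resident cases enter the numerator while
  denominators remain catchment population (a known, documented bias source).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaseRecord",
    "ExclusionReason",
    "ExclusionLog",
    "HIP_SITE_CODES",
    "UNSPECIFIED_SITE_CODE",
    "AGE_BAND_EDGES",
    "MIN_AGE",
    "TOP_BAND_LOW",
    "band_low_for_age",
    "band_label",
    "filter_cases",
    "tabulate_incidence",
    "amalgamate",
]

#: ICD-10 codes that identify a hip fracture site directly.
HIP_SITE_CODES = frozenset({"S72.0", "S72.1", "S72.2"})
#: Unspecified site of femoral fracture; included only with hip surgery.
UNSPECIFIED_SITE_CODE = "S72.9"

MIN_AGE = 40
TOP_BAND_LOW = 95
#: Lower edges of the half-open 5-year bands [lo, lo+5); top band is 95+.
AGE_BAND_EDGES = tuple(range(MIN_AGE, TOP_BAND_LOW + 1, 5))

VALID_SEXES = ("female", "male")
VALID_SOURCES = ("ambulance", "hospital", "outpatient")

#: Same-site re-admissions within this window count as one fracture.
DEDUP_WINDOW_DAYS = 365
#: Re-admissions within this gap are the same treatment episode (duplicate);
#: longer gaps that cross a calendar year boundary are prior-year fractures.
SAME_EPISODE_DAYS = 90


@dataclass(frozen=True)
class CaseRecord:
    """One admission or contact event in a fracture registry."""

    patient_id: str
    region: str
    sex: str
    age_years: int
    admission_date: _dt.date
    icd10_code: str
    hip_surgery: bool = False
    neoplasia: bool = False
    refused_hospitalization: bool = False
    source: str = "hospital"

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValueError(
                f"unknown sex {self.sex!r} for patient {self.patient_id!r}; "
                f"expected one of {VALID_SEXES}"
            )
        if self.age_years < 0:
            raise ValueError(
                f"negative age {self.age_years} for patient {self.patient_id!r}"
            )
        if not isinstance(self.admission_date, _dt.date):
            raise ValueError(
                f"admission_date for patient {self.patient_id!r} is not a date"
            )
        if self.source not in VALID_SOURCES:
            raise ValueError(
                f"unknown source {self.source!r} for patient {self.patient_id!r}"
            )


class ExclusionReason(str, Enum):
    DUPLICATE_SAME_FRACTURE = "duplicate_same_fracture"
    NEOPLASIA = "neoplasia"
    S729_NO_SURGERY = "s729_no_surgery"
    PRIOR_YEAR_SAME_SITE = "prior_year_same_site"
    NON_HIP_CODE = "non_hip_code"
    UNDER_AGE = "under_age"


@dataclass
class ExclusionLog:
    """Per-record drop log; ``included + excluded == input`` always holds."""

    entries: list[tuple[CaseRecord, ExclusionReason]] = field(default_factory=list)

    def add(self, record: CaseRecord, reason: ExclusionReason) -> None:
        self.entries.append((record, reason))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {r.value: 0 for r in ExclusionReason}
        for _, reason in self.entries:
            out[reason.value] += 1
        return out

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": rec.patient_id,
                "region": rec.region,
                "sex": rec.sex,
                "age_years": rec.age_years,
                "admission_date": rec.admission_date.isoformat(),
                "icd10_code": rec.icd10_code,
                "reason": reason.value,
            }
            for rec, reason in self.entries
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id",
                "region",
                "sex",
                "age_years",
                "admission_date",
                "icd10_code",
                "reason",
            ],
        )


def band_low_for_age(age: int) -> int:
    """Lower edge of the 5-year band containing ``age`` (top band open)."""
    if age < MIN_AGE:
        raise ValueError(f"age {age} below the ascertainment minimum {MIN_AGE}")
    return min(TOP_BAND_LOW, MIN_AGE + 5 * ((age - MIN_AGE) // 5))


def band_label(band_low: int) -> str:
    if band_low >= TOP_BAND_LOW:
        return f"{TOP_BAND_LOW}+"
    return f"{band_low}-{band_low + 4}"


def _record_sort_key(rec: CaseRecord):
    return (
        rec.admission_date,
        rec.patient_id,
        rec.icd10_code,
        rec.region,
        rec.source,
        rec.age_years,
    )


def filter_cases(
    records: Iterable[CaseRecord], *, min_age: int = MIN_AGE
) -> tuple[list[CaseRecord], ExclusionLog]:
    """Apply the case inclusion/exclusion rules.

    Returns the retained records (sorted by admission date, patient and
    code, so the result is independent of the input ordering) and an
    :class:`ExclusionLog` with exactly one reason per dropped record.

    Rule order per record: site code, unspecified-site-without-surgery,
    neoplasia, age; temporal deduplication runs last over the survivors of
    the row-level rules.

    Parameters
    ----------
    min_age : ascertainment floor in years; defaults to 40, the model's
        lower age limit.  A regional study that enrolled from a higher age
        may pass its own floor.
    """
    log = ExclusionLog()
    survivors: list[CaseRecord] = []
    for rec in records:
        if rec.icd10_code not in HIP_SITE_CODES and rec.icd10_code != UNSPECIFIED_SITE_CODE:
            log.add(rec, ExclusionReason.NON_HIP_CODE)
        elif rec.icd10_code == UNSPECIFIED_SITE_CODE and not rec.hip_surgery:
            log.add(rec, ExclusionReason.S729_NO_SURGERY)
        elif rec.neoplasia:
            log.add(rec, ExclusionReason.NEOPLASIA)
        elif rec.age_years < min_age:
            log.add(rec, ExclusionReason.UNDER_AGE)
        else:
            survivors.append(rec)

    # Temporal deduplication: one fracture per (patient, site code) per
    # 365-day window; the earliest admission is retained.
    included: list[CaseRecord] = []
    groups: dict[tuple[str, str], list[CaseRecord]] = {}
    for rec in sorted(survivors, key=_record_sort_key):
        groups.setdefault((rec.patient_id, rec.icd10_code), []).append(rec)
    for group in groups.values():
        last_retained: CaseRecord | None = None
        for rec in group:
            if last_retained is not None:
                gap = (rec.admission_date - last_retained.admission_date).days
                if gap < DEDUP_WINDOW_DAYS:
                    if (
                        gap > SAME_EPISODE_DAYS
                        and last_retained.admission_date.year < rec.admission_date.year
                    ):
                        log.add(rec, ExclusionReason.PRIOR_YEAR_SAME_SITE)
                    else:
                        log.add(rec, ExclusionReason.DUPLICATE_SAME_FRACTURE)
                    continue
            included.append(rec)
            last_retained = rec
    included.sort(key=_record_sort_key)
    return included, log


def _check_population(population: pd.DataFrame) -> pd.DataFrame:
    required = {"region", "sex", "age_low", "person_count"}
    missing = required - set(population.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    if (population["person_count"] < 0).any():
        raise ValueError("population counts must be non-negative")
    return population


def tabulate_incidence(
    included: Sequence[CaseRecord],
    population: pd.DataFrame,
    region: str,
    observation_years: float = 1.0,
) -> pd.DataFrame:
    """Banded incidence for one region.

    One row per (sex, 5-year band) covered by the population table;
    ``person_years = person_count * observation_years`` and
    ``rate = n_cases / person_years``.  A case falling in a band with zero
    recorded population is an error (no rate can be formed).
    """
    if observation_years <= 0:
        raise ValueError("observation_years must be positive")
    _check_population(population)
    pop = population[population["region"] == region]
    if pop.empty:
        raise ValueError(f"population table has no rows for region {region!r}")

    counts: dict[tuple[str, int], int] = {}
    for rec in included:
        if rec.region != region:
            continue
        key = (rec.sex, band_low_for_age(rec.age_years))
        counts[key] = counts.get(key, 0) + 1

    covered = {(r.sex, int(r.age_low)) for r in pop.itertuples()}
    uncovered = sorted(set(counts) - covered)
    if uncovered:
        raise ValueError(
            f"cases fall in bands absent from the population table: {uncovered}"
        )

    rows = []
    for r in pop.sort_values(["sex", "age_low"]).itertuples():
        key = (r.sex, int(r.age_low))
        n = counts.get(key, 0)
        py = float(r.person_count) * observation_years
        if n > 0 and py == 0:
            raise ValueError(
                f"{n} case(s) in band {band_label(int(r.age_low))} ({r.sex}, "
                f"region {region!r}) with zero recorded population"
            )
        rows.append(
            {
                "region": region,
                "sex": r.sex,
                "age_low": int(r.age_low),
                "age_high": float(r.age_high) if "age_high" in pop.columns else np.inf,
                "n_cases": n,
                "person_years": py,
                "rate": n / py if py > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def amalgamate(
    tables: Sequence[pd.DataFrame], populations: pd.DataFrame
) -> pd.DataFrame:
    """Pool regional incidence tables weighted by catchment population.

    Pooled rate per (sex, band) is ``sum_r(rate_r * pop_r) / sum_r(pop_r)``;
    for equal-length observation windows this equals pooling raw numerators
    and denominators.  Numerators and person-years are carried through.
    """
    if len(tables) == 0:
        raise ValueError("need at least one incidence table")
    _check_population(populations)

    base = tables[0][["sex", "age_low"]].drop_duplicates().sort_values(["sex", "age_low"])
    base_keys = list(map(tuple, base.to_numpy()))
    for t in tables[1:]:
        keys = list(
            map(tuple, t[["sex", "age_low"]].drop_duplicates().sort_values(["sex", "age_low"]).to_numpy())
        )
        if keys != base_keys:
            raise ValueError("incidence tables have mismatched band structures")

    pop_lookup = {
        (r.region, r.sex, int(r.age_low)): float(r.person_count)
        for r in populations.itertuples()
    }
    rows = []
    for sex, age_low in base_keys:
        num = 0.0
        wsum = 0.0
        n_cases = 0
        person_years = 0.0
        age_high = np.inf
        for t in tables:
            sub = t[(t["sex"] == sex) & (t["age_low"] == age_low)]
            if sub.empty:
                continue
            r = sub.iloc[0]
            region = r["region"]
            w = pop_lookup.get((region, sex, int(age_low)))
            if w is None:
                raise ValueError(
                    f"no catchment population for region {region!r}, "
                    f"sex {sex}, band {band_label(int(age_low))}"
                )
            num += float(r["rate"]) * w
            wsum += w
            n_cases += int(r["n_cases"])
            person_years += float(r["person_years"])
            age_high = float(r.get("age_high", np.inf))
        rows.append(
            {
                "region": "pooled",
                "sex": sex,
                "age_low": int(age_low),
                "age_high": age_high,
                "n_cases": n_cases,
                "person_years": person_years,
                "rate": num / wsum if wsum > 0 else 0.0,
            }
        )
    return pd.DataFrame(rows)
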