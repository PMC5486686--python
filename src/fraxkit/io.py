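"""CSV/JSON readers and writers, pipeline configuration and orchestration.

All artifacts are plain text: comma-separated UTF-8 CSV with a header row
and '.' decimal separator; dates ISO-8601; models and manifests JSON.  Every
writer here has a matching reader (outputs are closed under round trip).
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ascertainment import (
    CaseRecord,
    ExclusionLog,
    amalgamate,
    filter_cases,
    tabulate_incidence,
)
from .comparison import compare_models
from .hazards import CountryModel, RiskModelConfig, example_risk_config, hazard_table
from .incidence import fit_piecewise_loglinear
from .synthetic import (
    RegistrySimConfig,
    default_sim_config,
    generate_mortality,
    generate_population,
    generate_reference_model,
    generate_registry,
)

__all__ = [
    "read_registry",
    "write_registry",
    "read_population",
    "write_population",
    "read_incidence",
    "write_incidence",
    "read_mortality",
    "write_mortality",
    "write_exclusions",
    "load_demo_registry",
    "demo_registry_path",
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
]

logger = logging.getLogger("fraxkit")

REGISTRY_COLUMNS = [
    "patient_id",
    "region",
    "sex",
    "age_years",
    "admission_date",
    "icd10_code",
    "hip_surgery",
    "neoplasia",
    "refused_hospitalization",
    "source",
]

_ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d)?$")
_SEX_ALIASES = {"f": "female", "female": "female", "m": "male", "male": "male"}
_BOOL_ALIASES = {
    "true": True, "1": True, "yes": True,
    "false": False, "0": False, "no": False, "": False,
}


def _parse_bool(token: str, row: int, column: str) -> bool:
    try:
        return _BOOL_ALIASES[str(token).strip().lower()]
    except KeyError:
        raise ValueError(f"row {row}: bad boolean {token!r} in column {column!r}")


def read_registry(path) -> list[CaseRecord]:
    """Parse a registry CSV into typed records.

    Errors name the offending row (1-based, excluding the header) and column.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry {path}: missing columns {sorted(missing)}")
    records = []
    for i, raw in enumerate(df.itertuples(index=False), start=1):
        row = raw._asdict()
        sex = _SEX_ALIASES.get(row["sex"].strip().lower())
        if sex is None:
            raise ValueError(f"row {i}: unknown sex {row['sex']!r} in column 'sex'")
        try:
            date = _dt.date.fromisoformat(row["admission_date"].strip())
        except ValueError:
            raise ValueError(
                f"row {i}: unparseable date {row['admission_date']!r} "
                f"in column 'admission_date'"
            )
        code = row["icd10_code"].strip()
        if not _ICD10_RE.match(code):
            raise ValueError(
                f"row {i}: bad ICD-10 token {code!r} in column 'icd10_code'"
            )
        try:
            age = int(row["age_years"])
        except ValueError:
            raise ValueError(
                f"row {i}: bad age {row['age_years']!r} in column 'age_years'"
            )
        records.append(
            CaseRecord(
                patient_id=row["patient_id"],
                region=row["region"],
                sex=sex,
                age_years=age,
                admission_date=date,
                icd10_code=code,
                hip_surgery=_parse_bool(row["hip_surgery"], i, "hip_surgery"),
                neoplasia=_parse_bool(row["neoplasia"], i, "neoplasia"),
                refused_hospitalization=_parse_bool(
                    row["refused_hospitalization"], i, "refused_hospitalization"
                ),
                source=row["source"].strip(),
            )
        )
    return records


def write_registry(records, path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "region": r.region,
            "sex": r.sex,
            "age_years": r.age_years,
            "admission_date": r.admission_date.isoformat(),
            "icd10_code": r.icd10_code,
            "hip_surgery": str(r.hip_surgery).lower(),
            "neoplasia": str(r.neoplasia).lower(),
            "refused_hospitalization": str(r.refused_hospitalization).lower(),
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=REGISTRY_COLUMNS).to_csv(path, index=False)


def write_population(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"region", "sex", "age_low", "person_count"} - set(df.columns)
    if missing:
        raise ValueError(f"population {path}: missing columns {sorted(missing)}")
    return df


def write_incidence(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_incidence(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sex", "age_low", "rate"} - set(df.columns)
    if missing:
        raise ValueError(f"incidence {path}: missing columns {sorted(missing)}")
    return df


def write_mortality(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_mortality(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"sex", "age", "hazard"} - set(df.columns)
    if missing:
        raise ValueError(f"mortality {path}: missing columns {sorted(missing)}")
    return hazard_table(df["sex"], df["age"], df["hazard"])


def write_exclusions(log: ExclusionLog, path) -> None:
    log.to_frame().to_csv(path, index=False)


def demo_registry_path() -> Path:
    """Path to the packaged 10-record demonstration registry, which
    exercises each exclusion rule exactly once."""
    return Path(__file__).parent / "data" / "demo_registry.csv"


def load_demo_registry() -> list[CaseRecord]:
    return read_registry(demo_registry_path())


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    With ``simulate=True`` the registry, population and mortality inputs are
    generated into the output directory first; otherwise the given paths
    must exist.
    """

    output_dir: str = "fraxkit_run"
    seed: int = 0
    simulate: bool = True
    registry_path: str | None = None
    population_path: str | None = None
    mortality_path: str | None = None
    risk_config_path: str | None = None
    observation_years: float = 1.0
    knot_age: float = 67.0
    comparison_scale: float = 0.4
    ages: tuple = (50, 60, 70, 80)
    sim: dict = field(default_factory=dict)
    verbosity: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run simulate → ascertain → fit → build → compare, writing every
    artifact plus a manifest to ``config.output_dir``.

    Returns the output directory.  Any stage error aborts with the stage
    name and cause.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Stage:
            def __enter__(self):
                logger.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return _Stage()

    with stage("simulate"):
        if config.simulate:
            sim_cfg = default_sim_config(seed=config.seed, **config.sim)
            records, truth = generate_registry(sim_cfg)
            population = generate_population(sim_cfg)
            mortality = generate_mortality(
                alpha={"female": 1.6e-5, "male": 3.5e-5}, beta=0.095
            )
            registry_path = out / "registry.csv"
            population_path = out / "population.csv"
            mortality_path = out / "mortality.csv"
            write_registry(records, registry_path)
            write_population(population, population_path)
            write_mortality(mortality, mortality_path)
            truth.to_json(out / "sim_truth.json")
        else:
            registry_path = Path(config.registry_path)
            population_path = Path(config.population_path)
            mortality_path = Path(config.mortality_path)

    with stage("ascertain"):
        records = read_registry(registry_path)
        population = read_population(population_path)
        included, log = filter_cases(records)
        write_exclusions(log, out / "exclusions.csv")
        regions = sorted(population["region"].unique())
        tables = [
            tabulate_incidence(included, population, region, config.observation_years)
            for region in regions
        ]
        pooled = amalgamate(tables, population)
        write_incidence(pooled, out / "incidence.csv")

    with stage("fit-incidence"):
        models = fit_piecewise_loglinear(pooled, knot_age=config.knot_age)
        for sex, m in models.items():
            logger.info(
                "fit %s: intercept=%.4f slope_pre=%.4f slope_post=%.4f rss=%.4g",
                sex, m.intercept, m.slope_pre, m.slope_post, m.rss,
            )

    with stage("build-model"):
        mortality = read_mortality(mortality_path)
        if config.risk_config_path:
            with open(config.risk_config_path) as fh:
                risk = RiskModelConfig.from_dict(json.load(fh))
        else:
            risk = example_risk_config()
        model_a = CountryModel(hip=models, death=mortality, risk=risk)
        model_a.to_json(out / "model_a.json")
        model_b = generate_reference_model(model_a, config.comparison_scale)
        model_b.to_json(out / "model_b.json")

    with stage("compare"):
        report = compare_models(model_a, model_b, ages=tuple(config.ages))
        report.to_csv(out / "report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=2)

    with stage("manifest"):
        outputs = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "package": "fraxkit",
            "version": __version__,
            "seed": config.seed,
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "outputs": {name: _sha256(out / name) for name in outputs},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
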