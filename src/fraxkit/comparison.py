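"""Comparison of two fracture-probability models over clinical-scenario grids.

Two FRAX-style models are compared not on a population sample but on the
exhaustive array of clinical scenarios: every combination of k dichotomous
risk factors with m femoral-neck T-score levels (conventionally six factors
and T-scores 0 to -3.5 SD in 0.5 SD steps: 2^6 x 8 = 512 scenarios), at BMI
25 kg/m2, for each age/sex/outcome of interest.  The machinery here mirrors
how such comparisons are reported:

* the paired probabilities (model A, model B) for every scenario;
* a continuous piecewise-linear regression of B on A with fixed knots
  (defaults: 50% and 70% of the model-A probability for the MOF outcome,
  5% and 20% for hip fracture, chosen because the two outcomes occupy very
  different probability ranges);
* a percentile table at the 10th, 50th and 90th percentile of the model-A
  distribution, giving the model-B central estimate (the regression fit)
  with a 95% tolerance interval; and
* summary statistics (Pearson correlation, median relative difference).

Tolerance intervals are, by default, the empirical 2.5th-97.5th percentile
range of model-B probabilities among scenarios whose model-A probability
falls within +/-2 percentile ranks of the target percentile — a
nonparametric, reproducible construction.  A regression prediction-interval
alternative is available via ``interval="prediction"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hazards import (
    CLINICAL_RISK_FACTORS,
    DEFAULT_STEP_YEARS,
    MAX_AGE,
    CountryModel,
    RiskFactorProfile,
    TEN_YEAR_AGE_RANGE,
    _integrate_competing,
    risk_multiplier,
)

__all__ = [
    "ScenarioGrid",
    "PiecewiseFit",
    "build_grid",
    "evaluate_grid",
    "grid_probabilities",
    "piecewise_compare_regression",
    "percentile_table",
    "summarize",
    "compare_models",
    "DEFAULT_COMPARISON_FACTORS",
    "DEFAULT_TSCORES",
    "DEFAULT_KNOTS",
    "DEFAULT_AGES",
    "format_percent",
]

#: Six dichotomous factors used in the scenario grid; secondary
#: osteoporosis is omitted because BMD is entered in every scenario.
DEFAULT_COMPARISON_FACTORS = tuple(
    f for f in CLINICAL_RISK_FACTORS if f != "secondary_osteoporosis"
)
#: T-score levels 0 to -3.5 SD in 0.5 SD steps.
DEFAULT_TSCORES = tuple(np.arange(0.0, -4.0, -0.5))
#: Regression knots (as probability fractions) per outcome.
DEFAULT_KNOTS = {"mof": (0.50, 0.70), "hip": (0.05, 0.20)}
DEFAULT_AGES = (50, 60, 70, 80)
DEFAULT_PERCENTILES = (10, 50, 90)


@dataclass
class ScenarioGrid:
    """Exhaustive array of clinical scenarios at one age and sex."""

    age: float
    sex: str
    risk_factors: tuple[str, ...]
    tscores: tuple[float, ...]
    bmi: float = 25.0
    profiles: list[RiskFactorProfile] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.profiles)


def build_grid(
    risk_factors,
    tscores,
    age: float,
    sex: str,
    bmi: float = 25.0,
) -> ScenarioGrid:
    """All 2^k x m combinations of k binary factors and m T-score levels.

    Ordering is deterministic: T-score outermost, factor combinations as a
    binary counter (factor i toggled by bit i).
    """
    risk_factors = tuple(risk_factors)
    if len(set(risk_factors)) != len(risk_factors):
        raise ValueError("duplicate risk-factor names in grid definition")
    unknown = set(risk_factors) - set(CLINICAL_RISK_FACTORS)
    if unknown:
        raise ValueError(f"unknown risk factors: {sorted(unknown)}")
    tscores = tuple(float(t) for t in tscores)
    if len(set(tscores)) != len(tscores):
        raise ValueError("T-score levels must be distinct")
    if len(tscores) < 1:
        raise ValueError("need at least one T-score level")

    profiles = []
    k = len(risk_factors)
    for t in tscores:
        for mask in range(2**k):
            flags = {
                risk_factors[i]: bool((mask >> i) & 1) for i in range(k)
            }
            profiles.append(
                RiskFactorProfile(age=age, sex=sex, bmi=bmi, tscore=t, **flags)
            )
    return ScenarioGrid(
        age=age, sex=sex, risk_factors=risk_factors, tscores=tscores,
        bmi=bmi, profiles=profiles,
    )


def grid_probabilities(
    model: CountryModel,
    grid: ScenarioGrid,
    outcome: str = "mof",
    horizon: str = "ten_year",
    step: float = DEFAULT_STEP_YEARS,
) -> np.ndarray:
    """Probability for every scenario in the grid under one model.

    All scenarios share the baseline hazard, so the competing-risk integral
    is evaluated once as a (scenarios x steps) array scaled by each
    scenario's risk multiplier.
    """
    sex, age = grid.sex, grid.age
    if horizon == "ten_year":
        lo, hi = TEN_YEAR_AGE_RANGE
        if not lo <= age <= hi:
            raise ValueError(
                f"10-year outputs are supported for start ages {lo:.0f}-{hi:.0f}"
            )
        horizon_years = 10.0
    elif horizon == "lifetime":
        horizon_years = MAX_AGE - age
    else:
        raise ValueError("horizon must be 'ten_year' or 'lifetime'")

    n = max(1, int(round(horizon_years / step)))
    dt = horizon_years / n
    mid = age + (np.arange(n) + 0.5) * dt
    base = np.asarray(model.hip_hazard(sex)(mid), dtype=float)
    if outcome == "mof":
        base = base * model.risk.ratio_fn(sex)(mid)
    elif outcome != "hip":
        raise ValueError("outcome must be 'hip' or 'mof'")
    hd = np.asarray(model.death_hazard(sex)(mid), dtype=float)
    mults = np.array(
        [risk_multiplier(p, model.risk, outcome) for p in grid.profiles]
    )
    hf = mults[:, None] * base[None, :]
    return _integrate_competing(hf, hd[None, :], dt)


def evaluate_grid(
    model_a: CountryModel,
    model_b: CountryModel,
    grid: ScenarioGrid,
    outcome: str = "mof",
    horizon: str = "ten_year",
    step: float = DEFAULT_STEP_YEARS,
) -> pd.DataFrame:
    """Paired probabilities (p_a, p_b), one row per scenario, grid order."""
    p_a = grid_probabilities(model_a, grid, outcome, horizon, step)
    p_b = grid_probabilities(model_b, grid, outcome, horizon, step)
    k = len(grid.risk_factors)
    n_per_t = 2**k
    return pd.DataFrame(
        {
            "scenario": np.arange(len(grid)),
            "tscore": np.repeat(grid.tscores, n_per_t),
            "factor_mask": np.tile(np.arange(n_per_t), len(grid.tscores)),
            "p_a": p_a,
            "p_b": p_b,
        }
    )


@dataclass
class PiecewiseFit:
    """Continuous piecewise-linear least-squares fit of p_b on p_a."""

    knots: tuple[float, ...]
    coef: np.ndarray  # [intercept, base slope, hinge increments...]
    fitted: np.ndarray
    rss: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        out = self.coef[0] + self.coef[1] * x
        for j, k in enumerate(self.knots):
            out = out + self.coef[2 + j] * np.maximum(x - k, 0.0)
        return out

    @property
    def segment_slopes(self) -> np.ndarray:
        return np.cumsum(np.concatenate([[self.coef[1]], self.coef[2:]]))


def _design(x: np.ndarray, knots) -> np.ndarray:
    cols = [np.ones_like(x), x]
    cols += [np.maximum(x - k, 0.0) for k in knots]
    return np.column_stack(cols)


def piecewise_compare_regression(
    pairs: pd.DataFrame, knots=(0.5, 0.7)
) -> PiecewiseFit:
    """Fit p_b = f(p_a) with f continuous piecewise-linear, hinges at the
    knots.  Knots outside the observed p_a range are dropped with a warning.
    """
    x = pairs["p_a"].to_numpy(dtype=float)
    y = pairs["p_b"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs for a piecewise regression")
    if np.ptp(x) == 0:
        raise ValueError("all model-A probabilities identical; no regression possible")
    knots = tuple(sorted(float(k) for k in knots))
    if any(k2 <= k1 for k1, k2 in zip(knots, knots[1:])):
        raise ValueError("knots must be strictly increasing")
    usable = tuple(k for k in knots if x.min() < k < x.max())
    dropped = set(knots) - set(usable)
    if dropped:
        warnings.warn(
            f"knots outside the data range dropped: {sorted(dropped)}",
            stacklevel=2,
        )
    X = _design(x, usable)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ coef
    return PiecewiseFit(
        knots=usable,
        coef=coef,
        fitted=fitted,
        rss=float(np.sum((y - fitted) ** 2)),
    )


def percentile_table(
    pairs: pd.DataFrame,
    percentiles=DEFAULT_PERCENTILES,
    knots=(0.5, 0.7),
    interval: str = "tolerance",
    rank_window: float = 2.0,
) -> pd.DataFrame:
    """Model-A percentiles with model-B central estimates and 95% intervals.

    For each requested percentile q of the model-A distribution (linear
    interpolation between order statistics) the row reports the model-A
    value, the model-B central estimate (fitted value of the piecewise
    regression at that point) and a 95% interval:

    * ``interval="tolerance"`` (default): empirical 2.5-97.5 percentile range
      of model-B values among scenarios whose model-A percentile rank lies
      within ``rank_window`` ranks of q;
    * ``interval="prediction"``: 95% observation prediction interval from an
      OLS fit of the same piecewise design (statsmodels).
    """
    x = pairs["p_a"].to_numpy(dtype=float)
    y = pairs["p_b"].to_numpy(dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 pairs for a percentile table")

    degenerate = np.ptp(x) == 0
    fit = None
    sm_fit = None
    if not degenerate:
        fit = piecewise_compare_regression(pairs, knots)
        if interval == "prediction":
            import statsmodels.api as sm

            sm_fit = sm.OLS(y, _design(x, fit.knots)).fit()
    elif interval == "prediction":
        raise ValueError("prediction intervals need varying model-A values")

    ranks = (stats.rankdata(x) - 0.5) / len(x) * 100.0
    rows = []
    for q in percentiles:
        xa = float(np.percentile(x, q))
        if degenerate:
            central = float(y[0])
        else:
            central = float(fit.predict(xa))
        if interval == "tolerance":
            if degenerate:
                # all scenarios share one model-A value: the neighbourhood
                # is the whole tied mass
                mask = np.ones(len(x), dtype=bool)
            else:
                mask = np.abs(ranks - q) <= rank_window
            if mask.sum() < 2:
                raise ValueError(
                    f"fewer than 2 scenarios within {rank_window} percentile "
                    f"ranks of the {q}th percentile; cannot form an interval"
                )
            lo, hi = np.percentile(y[mask], [2.5, 97.5])
        elif interval == "prediction":
            pred = sm_fit.get_prediction(_design(np.array([xa]), fit.knots))
            lo, hi = map(float, pred.conf_int(obs=True, alpha=0.05)[0])
        else:
            raise ValueError("interval must be 'tolerance' or 'prediction'")
        rows.append(
            {
                "percentile": q,
                "p_a": xa,
                "p_b": central,
                "ti_low": float(lo),
                "ti_high": float(hi),
            }
        )
    return pd.DataFrame(rows)


def summarize(pairs: pd.DataFrame) -> dict[str, float]:
    """Pearson correlation and signed median relative difference (%).

    The relative difference is (p_a - p_b)/p_a per scenario; its median is
    reported as a percentage (positive when model B runs lower).
    """
    x = pairs["p_a"].to_numpy(dtype=float)
    y = pairs["p_b"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(x > 0, (x - y) / x, np.nan)
    return {
        "pearson_r": r,
        "median_relative_difference_pct": float(np.nanmedian(rel) * 100.0),
    }


def format_percent(p: float) -> str:
    """Render a probability fraction as a percentage: 1 decimal below 10%,
    0 decimals at or above."""
    pct = 100.0 * p
    return f"{pct:.0f}" if pct >= 10 else f"{pct:.1f}"


def compare_models(
    model_a: CountryModel,
    model_b: CountryModel,
    ages=DEFAULT_AGES,
    sexes=("female", "male"),
    outcomes=("mof", "hip"),
    risk_factors=DEFAULT_COMPARISON_FACTORS,
    tscores=DEFAULT_TSCORES,
    percentiles=DEFAULT_PERCENTILES,
    knots_by_outcome=None,
    interval: str = "tolerance",
    step: float = DEFAULT_STEP_YEARS,
) -> pd.DataFrame:
    """Full comparison report over ages x sexes x outcomes (long format).

    One row per (age, sex, outcome, percentile) with the model-A value, the
    model-B central estimate, its 95% interval, and per-cell Pearson r and
    median relative difference.
    """
    if knots_by_outcome is None:
        knots_by_outcome = DEFAULT_KNOTS
    rows = []
    for sex in sexes:
        for age in ages:
            grid = build_grid(risk_factors, tscores, age, sex)
            for outcome in outcomes:
                pairs = evaluate_grid(model_a, model_b, grid, outcome, step=step)
                table = percentile_table(
                    pairs,
                    percentiles=percentiles,
                    knots=knots_by_outcome[outcome],
                    interval=interval,
                )
                summary = summarize(pairs)
                for rec in table.to_dict(orient="records"):
                    rows.append(
                        {
                            "age": age,
                            "sex": sex,
                            "outcome": outcome,
                            **rec,
                            "pearson_r": summary["pearson_r"],
                            "median_relative_difference_pct": summary[
                                "median_relative_difference_pct"
                            ],
                        }
                    )
    return pd.DataFrame(rows)
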