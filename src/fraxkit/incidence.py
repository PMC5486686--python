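"""Smoothing banded incidence into a continuous-age hazard.

Five-year banded hip-fracture rates are smoothed by piecewise linear
regression of log-transformed rates on age, with a fixed breakpoint at 67
years and continuity enforced at the knot.  The fitted exponent gives a
hazard at any exact age in [40, 110], which is what the probability engine
integrates.

The model is

    log h(a) = b0 + b1 * (min(a, k) - 40) + b2 * max(a - k, 0)

with knot ``k`` (default 67), intercept ``b0`` the log-rate at the
reference age 40, pre-knot slope ``b1`` and post-knot slope ``b2`` per year.
Regression abscissae are band midpoints (42.5 for [40,45), ...); the open
top band uses its lower edge + 2.5.  Zero-rate bands are dropped from the
log-scale fit with a warning.  The fit is unweighted least squares by
default, with optional case-count weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PiecewiseLogLinearModel",
    "fit_piecewise_loglinear",
    "predict_rate",
    "DEFAULT_KNOT_AGE",
    "REFERENCE_AGE",
    "AGE_RANGE",
]

DEFAULT_KNOT_AGE = 67.0
REFERENCE_AGE = 40.0
#: Ages over which a fitted hazard may be evaluated.
AGE_RANGE = (40.0, 110.0)


@dataclass(frozen=True)
class PiecewiseLogLinearModel:
    """Continuous-age hazard: two log-linear segments joined at a knot."""

    sex: str
    intercept: float
    slope_pre: float
    slope_post: float
    knot_age: float = DEFAULT_KNOT_AGE
    rss: float = float("nan")
    n_points: int = 0

    def log_rate(self, age):
        age = np.asarray(age, dtype=float)
        pre = np.minimum(age, self.knot_age) - REFERENCE_AGE
        post = np.maximum(age - self.knot_age, 0.0)
        return self.intercept + self.slope_pre * pre + self.slope_post * post

    def rate(self, age):
        """Hazard per person-year at exact age(s); ages must lie in [40, 110]."""
        arr = np.asarray(age, dtype=float)
        if np.any(arr < AGE_RANGE[0]) or np.any(arr > AGE_RANGE[1]):
            raise ValueError(
                f"age outside the supported range {AGE_RANGE}: {age!r}"
            )
        out = np.exp(self.log_rate(arr))
        return float(out) if np.isscalar(age) or arr.ndim == 0 else out

    def scaled(self, factor: float) -> "PiecewiseLogLinearModel":
        """Model with the hazard multiplied by ``factor`` at every age."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return PiecewiseLogLinearModel(
            sex=self.sex,
            intercept=self.intercept + float(np.log(factor)),
            slope_pre=self.slope_pre,
            slope_post=self.slope_post,
            knot_age=self.knot_age,
            rss=self.rss,
            n_points=self.n_points,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PiecewiseLogLinearModel":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def band_midpoint(age_low: float, half_width: float = 2.5) -> float:
    return float(age_low) + half_width


def _fit_one(
    sex: str,
    ages: np.ndarray,
    rates: np.ndarray,
    knot_age: float,
    weights: np.ndarray | None,
) -> PiecewiseLogLinearModel:
    positive = rates > 0
    if np.any(~positive):
        warnings.warn(
            f"dropping {int(np.sum(~positive))} zero-rate band(s) from the "
            f"log-scale fit ({sex})",
            stacklevel=3,
        )
    ages = ages[positive]
    rates = rates[positive]
    if weights is not None:
        weights = weights[positive]
    if len(ages) < 3:
        raise ValueError(
            f"fewer than 3 positive-rate bands for sex {sex!r}: fit is underdetermined"
        )

    y = np.log(rates)
    x_pre = np.minimum(ages, knot_age) - REFERENCE_AGE
    x_post = np.maximum(ages - knot_age, 0.0)
    X = np.column_stack([np.ones_like(ages), x_pre, x_post])
    if weights is not None:
        sw = np.sqrt(weights)
        Xw, yw = X * sw[:, None], y * sw
    else:
        Xw, yw = X, y
    coef, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < 3:
        raise ValueError(
            f"design is rank-deficient for sex {sex!r}: need positive-rate "
            f"bands on both sides of the knot at {knot_age}"
        )
    resid = y - X @ coef
    return PiecewiseLogLinearModel(
        sex=sex,
        intercept=float(coef[0]),
        slope_pre=float(coef[1]),
        slope_post=float(coef[2]),
        knot_age=float(knot_age),
        rss=float(np.sum(resid**2)),
        n_points=int(len(ages)),
    )


def fit_piecewise_loglinear(
    table: pd.DataFrame,
    knot_age: float = DEFAULT_KNOT_AGE,
    weight_by_cases: bool = False,
) -> dict[str, PiecewiseLogLinearModel]:
    """Fit one two-segment log-linear model per sex to a banded incidence table.

    Parameters
    ----------
    table : incidence table with columns sex, age_low, rate (and n_cases if
        ``weight_by_cases``).
    knot_age : fixed breakpoint in years (default 67; not estimated).
    weight_by_cases : weight each band by its case count instead of the
        default unweighted least squares.

    Returns a mapping ``sex -> PiecewiseLogLinearModel``.
    """
    required = {"sex", "age_low", "rate"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"incidence table missing columns: {sorted(missing)}")
    models: dict[str, PiecewiseLogLinearModel] = {}
    for sex, sub in table.groupby("sex", sort=True):
        ages = np.array([band_midpoint(a) for a in sub["age_low"]], dtype=float)
        rates = sub["rate"].to_numpy(dtype=float)
        w = sub["n_cases"].to_numpy(dtype=float) if weight_by_cases else None
        models[str(sex)] = _fit_one(str(sex), ages, rates, knot_age, w)
    return models


def predict_rate(model: PiecewiseLogLinearModel, age) -> float:
    """Hazard per person-year at an exact age in [40, 110]."""
    return model.rate(age)
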