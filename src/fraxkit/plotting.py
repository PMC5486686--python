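"""A single diagnostic figure: observed banded rates vs the smoothed hazard."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .incidence import PiecewiseLogLinearModel, band_midpoint


def plot_incidence(
    table: pd.DataFrame,
    models: dict[str, PiecewiseLogLinearModel],
    path=None,
    per=10_000.0,
):
    """Observed 5-year-band incidence (symbols) with the fitted continuous
    piecewise log-linear hazard (lines), per ``per`` person-years, log scale.

    Returns the matplotlib figure; writes it to ``path`` if given.
    Requires matplotlib (the ``plot`` extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {"female": "tab:red", "male": "tab:blue"}
    ages = np.linspace(40, 100, 241)
    for sex, model in models.items():
        sub = table[table["sex"] == sex]
        mids = [band_midpoint(lo) for lo in sub["age_low"]]
        ax.semilogy(
            mids, sub["rate"] * per, "o", mfc="none",
            color=colors.get(sex, "k"), label=f"{sex} (observed)",
        )
        ax.semilogy(
            ages, model.rate(ages) * per, "-",
            color=colors.get(sex, "k"), label=f"{sex} (smoothed)",
        )
    ax.set_xlabel("Age (years)")
    ax.set_ylabel(f"Hip fractures per {per:,.0f} person-years")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
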