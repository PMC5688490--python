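"""Plotting helpers for cost projections."""

from __future__ import annotations

from typing import Optional

import pandas as pd

from . import engine
from .types import COMPONENTS


def plot_cost_components(results: pd.DataFrame, ax: Optional["object"] = None):
    """Stacked bars of scenario-total cost components by year.

    ``results`` is the tidy table from :func:`costkit.engine.scenario_costs`
    (must include the ``__all__`` total rows). Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    totals = results[results["intervention_id"] == engine.TOTAL_ROW_ID]
    if totals.empty:
        raise ValueError("results table has no scenario-total rows")
    wide = (
        totals[totals["component"] != "total"]
        .pivot(index="year", columns="component", values="usd")
        .reindex(columns=list(COMPONENTS))
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4.5))
    bottom = None
    for component in wide.columns:
        ax.bar(wide.index, wide[component], bottom=bottom, label=component)
        bottom = wide[component] if bottom is None else bottom + wide[component]
    ax.set_xlabel("year")
    ax.set_ylabel("cost (USD)")
    ax.legend(fontsize=8)
    return ax
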