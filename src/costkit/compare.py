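"""Scenario comparison and cost-effectiveness summaries.

Two scenarios over the same years and intervention set are compared
component-wise; incremental costs combined with externally supplied
lives-saved estimates yield cost-per-life-saved ratios and a league table
ranking interventions by incremental cost-effectiveness. Mortality impact
itself is an external input (a lives-saved CSV), keeping the impact engine
decoupled; health effects are not discounted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from . import engine
from .errors import ComparisonError, ScenarioValidationError, UndefinedRatioError
from .types import Scenario


@dataclass(frozen=True)
class ScenarioComparison:
    """Component-wise cost comparison of two scenarios.

    ``table`` has one row per (intervention_id, year, component) — including
    the scenario-total rows under intervention id ``__all__`` — with columns
    ``baseline_usd``, ``alternative_usd`` and ``incremental_usd``
    (alternative minus baseline; may be negative).
    """

    baseline_name: str
    alternative_name: str
    table: pd.DataFrame

    def grand_total(self) -> pd.Series:
        """Incremental cost summed over interventions and years, by component."""
        mask = self.table["intervention_id"] == engine.TOTAL_ROW_ID
        return self.table[mask].groupby("component")["incremental_usd"].sum()

    def incremental_by_intervention(self) -> pd.Series:
        """Total incremental cost per intervention, summed over years."""
        df = self.table
        mask = (df["intervention_id"] != engine.TOTAL_ROW_ID) & (
            df["component"] == "total"
        )
        return df[mask].groupby("intervention_id")["incremental_usd"].sum()

    def to_csv(self, path: Union[str, Path]) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False, lineterminator="\n")


def compare(baseline: Scenario, alternative: Scenario) -> ScenarioComparison:
    """Component-wise incremental costs of ``alternative`` over ``baseline``.

    The two scenarios must cover identical year ranges and intervention sets.
    """
    if baseline.year_range != alternative.year_range:
        raise ComparisonError(
            f"year ranges differ: {baseline.year_range} vs {alternative.year_range}"
        )
    if baseline.interventions != alternative.interventions:
        raise ComparisonError(
            f"intervention sets differ: {baseline.interventions} vs "
            f"{alternative.interventions}"
        )
    base = engine.scenario_costs(baseline).rename(columns={"usd": "baseline_usd"})
    alt = engine.scenario_costs(alternative).rename(columns={"usd": "alternative_usd"})
    merged = base.merge(
        alt, on=["intervention_id", "year", "component"], validate="one_to_one"
    )
    merged["incremental_usd"] = merged["alternative_usd"] - merged["baseline_usd"]
    return ScenarioComparison(
        baseline_name=baseline.name,
        alternative_name=alternative.name,
        table=merged,
    )


def cost_per_life_saved(
    incremental_cost: float, incremental_lives_saved: float
) -> float:
    """Incremental cost-effectiveness ratio in USD per life saved.

    Sign is preserved; a zero lives-saved denominator raises
    :class:`UndefinedRatioError` rather than returning an infinity.
    """
    if incremental_lives_saved == 0:
        raise UndefinedRatioError(
            "cost per life saved is undefined for zero incremental lives saved"
        )
    return incremental_cost / incremental_lives_saved


def league_table(
    comparison: ScenarioComparison, impacts: pd.DataFrame
) -> pd.DataFrame:
    """Rank interventions by incremental cost per life saved, ascending.

    ``impacts`` needs columns (scenario, intervention_id, year, lives_saved);
    incremental lives saved per intervention are the alternative-scenario
    rows minus the baseline rows (absent baseline rows count as zero), summed
    over years. Every compared intervention must have at least one impact row.

    Entries with non-positive incremental lives saved are flagged
    ``dominated`` and listed last (their ratio is reported when lives saved
    are negative, NaN when zero); ties on the ratio break lexicographically
    by intervention id. No row is ever dropped.
    """
    if "intervention_id" not in impacts.columns:
        raise ScenarioValidationError(
            "league_table requires per-intervention impact rows "
            "(impacts.csv with an intervention_id column)"
        )
    inc_cost = comparison.incremental_by_intervention()

    def _lives(scenario_name: str) -> pd.Series:
        sub = impacts[impacts["scenario"] == scenario_name]
        return sub.groupby("intervention_id")["lives_saved"].sum()

    alt_lives = _lives(comparison.alternative_name)
    base_lives = _lives(comparison.baseline_name)

    rows = []
    for iv in inc_cost.index:
        if iv not in alt_lives.index and iv not in base_lives.index:
            raise ScenarioValidationError(
                f"no impact row for intervention {iv!r}"
            )
        lives = float(alt_lives.get(iv, 0.0)) - float(base_lives.get(iv, 0.0))
        cost = float(inc_cost[iv])
        ratio = cost / lives if lives != 0 else math.nan
        rows.append(
            {
                "intervention_id": iv,
                "incremental_cost": cost,
                "incremental_lives_saved": lives,
                "cost_per_life_saved": ratio,
                "dominated": lives <= 0,
            }
        )
    df = pd.DataFrame(rows)
    ranked = df[~df["dominated"]].sort_values(
        ["cost_per_life_saved", "intervention_id"], kind="stable"
    )
    flagged = df[df["dominated"]].sort_values("intervention_id", kind="stable")
    return pd.concat([ranked, flagged], ignore_index=True)
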