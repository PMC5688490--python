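"""The ingredients-based costing engine.

The arithmetic follows the standard service-costing identities:

    services         = target population x fraction in need x effective coverage
    intervention cost = services x unit cost per case
    total cost        = sum of intervention costs + above-facility program costs

The unit cost per case is built bottom-up from treatment inputs: drug/supply
ingredient lines (unit price x units x fraction of clients receiving),
provider time (minutes x visits x cadre cost per productive minute), and the
other-direct / indirect portions of the country "hotel" cost of outpatient
visits and inpatient bed-days. Hotel costs bundle personnel, consumables,
other-direct and indirect components; only the other-direct and indirect
factor shares are applied here because personnel and consumables are already
ingredient-costed — applying all four would double count. Health-centre
shares apply to outpatient visits, hospital shares to inpatient days.

All quantities are linear in prices, wages, populations and coverage, and
service counts are kept as reals (rounding is a formatting concern).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .errors import DomainError
from .types import (
    CadreCost,
    ChannelProfile,
    CostBreakdown,
    DrugSupplyLine,
    FactorShares,
    HotelCostTable,
    InterventionProfile,
    ProgramCostSpec,
    ProviderTimeLine,
    Scenario,
    UnitCostDB,
    UnitCostPerCase,
    VisitProfile,
)

__all__ = [
    "services_count",
    "cost_per_minute",
    "drug_supply_cost_per_case",
    "labor_cost_per_case",
    "hotel_overhead_per_case",
    "unit_cost_per_case",
    "intervention_cost",
    "program_costs",
    "ProgramCostResult",
    "total_cost",
    "scenario_costs",
]


def services_count(
    population: float, need_fraction: float, coverage_fraction: float
) -> float:
    """Number of services delivered: population x need x coverage.

    ``need_fraction`` may exceed 1 (multiple cases per person-year);
    ``coverage_fraction`` may not.
    """
    if population < 0 or need_fraction < 0:
        raise DomainError(
            f"population and need_fraction must be non-negative, got "
            f"({population!r}, {need_fraction!r})"
        )
    if not 0.0 <= coverage_fraction <= 1.0:
        raise DomainError(
            f"coverage_fraction must be in [0, 1], got {coverage_fraction!r}"
        )
    return population * need_fraction * coverage_fraction


def cost_per_minute(cadre: CadreCost) -> float:
    """Cost of one delivered provider minute (USD/min).

    Annual remuneration divided by *productive* minutes: working days x
    minutes per day x utilization. Lower utilization therefore raises the
    effective cost per delivered minute.
    """
    denom = cadre.working_days_per_year * cadre.minutes_per_day * cadre.utilization
    if denom <= 0:
        raise DomainError(
            f"cadre {cadre.cadre_id!r}: non-positive productive minutes"
        )
    return cadre.annual_remuneration / denom


def drug_supply_cost_per_case(lines: Iterable[DrugSupplyLine]) -> float:
    """Ingredient cost per case: sum of price x units x fraction receiving."""
    return sum(
        line.unit_price * line.units_per_case * line.pct_receiving for line in lines
    )


def labor_cost_per_case(
    time_lines: Iterable[ProviderTimeLine], cadres: Mapping[str, CadreCost]
) -> float:
    """Provider-time cost per case summed over cadres."""
    total = 0.0
    for line in time_lines:
        if line.cadre_id not in cadres:
            raise DomainError(f"unknown cadre {line.cadre_id!r} in time line")
        total += (
            line.minutes_per_visit * line.n_visits * cost_per_minute(cadres[line.cadre_id])
        )
    return total


def hotel_overhead_per_case(
    profile: VisitProfile,
    hotel: HotelCostTable,
    shares_hospital: FactorShares,
    shares_health_centre: FactorShares,
) -> Tuple[float, float]:
    """Other-direct and indirect cost per case from visit/bed-day hotel costs.

    Outpatient visits take the health-centre shares, inpatient days the
    hospital shares. Returns ``(other_direct, indirect)`` in USD per case.
    The personnel and consumables portions of the hotel cost are deliberately
    not included (they are ingredient-costed elsewhere).
    """
    opv_usd = profile.opv_per_case * hotel.cost_per_opv
    ipd_usd = profile.ipd_per_case * hotel.cost_per_ipd
    other_direct = opv_usd * shares_health_centre.s_odc + ipd_usd * shares_hospital.s_odc
    indirect = (
        opv_usd * shares_health_centre.s_indirect + ipd_usd * shares_hospital.s_indirect
    )
    return other_direct, indirect


def _channel_unit_cost(channel: ChannelProfile, cost_db: UnitCostDB) -> UnitCostPerCase:
    other_direct, indirect = hotel_overhead_per_case(
        channel.visit_profile,
        cost_db.hotel,
        cost_db.shares["hospital"],
        cost_db.shares["health_centre"],
    )
    return UnitCostPerCase(
        drugs_supplies=drug_supply_cost_per_case(channel.drug_lines),
        labor=labor_cost_per_case(channel.time_lines, cost_db.cadres),
        other_direct=other_direct,
        indirect=indirect,
    )


def unit_cost_per_case(
    profile: InterventionProfile, cost_db: UnitCostDB
) -> UnitCostPerCase:
    """Channel-mix-weighted unit cost per case for one intervention."""
    drugs = labor = other_direct = indirect = 0.0
    for channel in profile.channels.values():
        unit = _channel_unit_cost(channel, cost_db)
        w = channel.mix_fraction
        drugs += w * unit.drugs_supplies
        labor += w * unit.labor
        other_direct += w * unit.other_direct
        indirect += w * unit.indirect
    return UnitCostPerCase(
        drugs_supplies=drugs, labor=labor, other_direct=other_direct, indirect=indirect
    )


def intervention_cost(
    intervention_id: str, year: int, scenario: Scenario
) -> CostBreakdown:
    """Facility-level cost of one intervention in one year.

    Sums services over the intervention's need rows for the year and scales
    each unit-cost component. ``above_facility`` is zero here: program costs
    are a scenario-level add-on (see :func:`total_cost`).
    """
    if intervention_id not in scenario.profiles:
        raise DomainError(f"unknown intervention {intervention_id!r}")
    if year not in scenario.years:
        raise DomainError(
            f"year {year} outside scenario range {scenario.year_range}"
        )
    rows = scenario.needs_for(intervention_id, year)
    if not rows:
        raise DomainError(
            f"no need/coverage rows for intervention {intervention_id!r} in {year}"
        )
    services = sum(
        services_count(
            scenario.population_count(r.pop_id, r.year),
            r.need_fraction,
            r.coverage_fraction,
        )
        for r in rows
    )
    unit = unit_cost_per_case(scenario.profiles[intervention_id], scenario.cost_db)
    return CostBreakdown.from_components(
        drugs_supplies=services * unit.drugs_supplies,
        labor=services * unit.labor,
        other_direct=services * unit.other_direct,
        indirect=services * unit.indirect,
        above_facility=0.0,
    )


@dataclass(frozen=True)
class ProgramCostResult:
    """Above-facility program costs by category plus their total (USD/year)."""

    by_category: Dict[str, float]
    total: float


def program_costs(spec: ProgramCostSpec, facility_total: float) -> ProgramCostResult:
    """Above-facility costs: fixed amounts pass through, markups scale the
    total facility-level cost (drugs included)."""
    if facility_total < 0:
        raise DomainError(f"facility_total must be >= 0, got {facility_total!r}")
    by_category: Dict[str, float] = {}
    for cat, item in spec.items.items():
        if item.fixed_amount is not None:
            by_category[cat] = item.fixed_amount
        else:
            by_category[cat] = item.markup_fraction * facility_total
    return ProgramCostResult(by_category=by_category, total=sum(by_category.values()))


def total_cost(scenario: Scenario, year: int) -> CostBreakdown:
    """Total annual cost: all interventions plus above-facility program costs."""
    if year not in scenario.years:
        raise DomainError(f"year {year} outside scenario range {scenario.year_range}")
    acc = CostBreakdown.zero()
    for iv in scenario.interventions:
        acc = acc + intervention_cost(iv, year, scenario)
    prog = program_costs(scenario.program_costs, acc.total)
    return CostBreakdown.from_components(
        drugs_supplies=acc.drugs_supplies,
        labor=acc.labor,
        other_direct=acc.other_direct,
        indirect=acc.indirect,
        above_facility=prog.total,
    )


TOTAL_ROW_ID = "__all__"


def scenario_costs(
    scenario: Scenario,
    year_from: Optional[int] = None,
    year_to: Optional[int] = None,
    include_totals: bool = True,
) -> pd.DataFrame:
    """Tidy per-intervention per-year cost table.

    One row per (intervention, year, component) including the component
    ``total``; when ``include_totals`` is set, per-year scenario totals are
    appended under intervention id ``__all__`` (the only rows carrying a
    nonzero ``above_facility`` component).
    """
    start = scenario.year_range[0] if year_from is None else year_from
    end = scenario.year_range[1] if year_to is None else year_to
    if start > end or start not in scenario.years or end not in scenario.years:
        raise DomainError(
            f"requested years [{start}, {end}] outside scenario range "
            f"{scenario.year_range}"
        )
    records = []
    for year in range(start, end + 1):
        for iv in scenario.interventions:
            breakdown = intervention_cost(iv, year, scenario)
            for component, usd in breakdown.as_dict().items():
                records.append(
                    {
                        "intervention_id": iv,
                        "year": year,
                        "component": component,
                        "usd": usd,
                    }
                )
        if include_totals:
            breakdown = total_cost(scenario, year)
            for component, usd in breakdown.as_dict().items():
                records.append(
                    {
                        "intervention_id": TOTAL_ROW_ID,
                        "year": year,
                        "component": component,
                        "usd": usd,
                    }
                )
    return pd.DataFrame.from_records(records)
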