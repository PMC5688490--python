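"""Test helpers: an independent brute-force costing oracle and scenario
transformations. The oracle enumerates every (need row x channel x line)
with plain Python arithmetic and never calls the engine's own operations."""

from __future__ import annotations

from typing import Dict

from costkit.defaults import DEFAULT_FACTOR_SHARES
from costkit.types import (
    CadreCost,
    ChannelProfile,
    DrugSupplyLine,
    HotelCostTable,
    InterventionProfile,
    NeedCoverage,
    ProgramCostItem,
    ProgramCostSpec,
    ProviderTimeLine,
    Scenario,
    TargetPopulation,
    UnitCostDB,
    VisitProfile,
)


def make_mini_scenario() -> Scenario:
    """One-intervention scenario with round numbers.

    services = 1,000,000 x 0.20 x 0.50 = 100,000; drug cost 0.50/case;
    labor 12.50/case (60 min at 12000/57600 USD/min); hotel overhead
    0.68 + 2.32 per case (4 OPV at 2.00 with default health-centre shares).
    """
    return Scenario(
        name="mini",
        year_range=(2030, 2030),
        populations=(
            TargetPopulation(pop_id="children", year=2030, count=1_000_000.0),
        ),
        needs=(
            NeedCoverage(
                intervention_id="ors",
                pop_id="children",
                year=2030,
                need_fraction=0.20,
                coverage_fraction=0.50,
            ),
        ),
        profiles={
            "ors": InterventionProfile(
                intervention_id="ors",
                channels={
                    "facility": ChannelProfile(
                        drug_lines=(
                            DrugSupplyLine(
                                item_id="sachet",
                                unit_price=0.05,
                                units_per_case=10,
                                pct_receiving=1.0,
                            ),
                        ),
                        time_lines=(
                            ProviderTimeLine(
                                cadre_id="nurse", minutes_per_visit=20, n_visits=3
                            ),
                        ),
                        visit_profile=VisitProfile(opv_per_case=4, ipd_per_case=0),
                        mix_fraction=1.0,
                    )
                },
            )
        },
        cost_db=UnitCostDB(
            cadres={
                "nurse": CadreCost(
                    cadre_id="nurse",
                    annual_remuneration=12_000.0,
                    working_days_per_year=240.0,
                    minutes_per_day=480.0,
                    utilization=0.5,
                )
            },
            hotel=HotelCostTable(cost_per_opv=2.0, cost_per_ipd=10.0),
            shares=dict(DEFAULT_FACTOR_SHARES),
        ),
        program_costs=ProgramCostSpec(
            items={"program_management": ProgramCostItem(markup_fraction=0.10)}
        ),
    )


def brute_force_costs(scenario: Scenario, year: int) -> Dict[str, float]:
    """Scenario-total cost components for one year by direct enumeration."""
    drugs = labor = other_direct = indirect = 0.0
    hc = scenario.cost_db.shares["health_centre"]
    hosp = scenario.cost_db.shares["hospital"]
    hotel = scenario.cost_db.hotel
    for iv, profile in scenario.profiles.items():
        services = 0.0
        for row in scenario.needs:
            if row.intervention_id != iv or row.year != year:
                continue
            pop = next(
                p.count
                for p in scenario.populations
                if p.pop_id == row.pop_id and p.year == year
            )
            services += pop * row.need_fraction * row.coverage_fraction
        for channel in profile.channels.values():
            w = channel.mix_fraction * services
            for line in channel.drug_lines:
                drugs += w * line.unit_price * line.units_per_case * line.pct_receiving
            for line in channel.time_lines:
                cadre = scenario.cost_db.cadres[line.cadre_id]
                per_min = cadre.annual_remuneration / (
                    cadre.working_days_per_year
                    * cadre.minutes_per_day
                    * cadre.utilization
                )
                labor += w * line.minutes_per_visit * line.n_visits * per_min
            opv_usd = channel.visit_profile.opv_per_case * hotel.cost_per_opv
            ipd_usd = channel.visit_profile.ipd_per_case * hotel.cost_per_ipd
            other_direct += w * (opv_usd * hc.s_odc + ipd_usd * hosp.s_odc)
            indirect += w * (opv_usd * hc.s_indirect + ipd_usd * hosp.s_indirect)
    facility = drugs + labor + other_direct + indirect
    above = 0.0
    for item in scenario.program_costs.items.values():
        if item.fixed_amount is not None:
            above += item.fixed_amount
        else:
            above += item.markup_fraction * facility
    return {
        "drugs_supplies": drugs,
        "labor": labor,
        "other_direct": other_direct,
        "indirect": indirect,
        "above_facility": above,
        "total": facility + above,
    }


def scale_prices(scenario: Scenario, k: float) -> Scenario:
    """Scenario with every drug price, wage and hotel cost multiplied by k."""
    profiles = {}
    for iv, profile in scenario.profiles.items():
        channels = {}
        for name, ch in profile.channels.items():
            channels[name] = ChannelProfile(
                drug_lines=tuple(
                    line.model_copy(update={"unit_price": line.unit_price * k})
                    for line in ch.drug_lines
                ),
                time_lines=ch.time_lines,
                visit_profile=ch.visit_profile,
                mix_fraction=ch.mix_fraction,
            )
        profiles[iv] = InterventionProfile(intervention_id=iv, channels=channels)
    cadres = {
        cid: c.model_copy(update={"annual_remuneration": c.annual_remuneration * k})
        for cid, c in scenario.cost_db.cadres.items()
    }
    hotel = scenario.cost_db.hotel.model_copy(
        update={
            "cost_per_opv": scenario.cost_db.hotel.cost_per_opv * k,
            "cost_per_ipd": scenario.cost_db.hotel.cost_per_ipd * k,
        }
    )
    return scenario.model_copy(
        update={
            "profiles": profiles,
            "cost_db": UnitCostDB(
                cadres=cadres, hotel=hotel, shares=scenario.cost_db.shares
            ),
        }
    )
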