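"""Unit tests for the costing arithmetic against hand-computed values."""

import math

import pytest

from costkit import engine
from costkit.defaults import DEFAULT_FACTOR_SHARES
from costkit.errors import DomainError
from costkit.types import (
    CadreCost,
    ChannelProfile,
    DrugSupplyLine,
    FactorShares,
    HotelCostTable,
    InterventionProfile,
    ProgramCostItem,
    ProgramCostSpec,
    ProviderTimeLine,
    UnitCostDB,
    VisitProfile,
)

from helpers import brute_force_costs


def _cadre(remuneration=12_000.0, days=240.0, minutes=480.0, utilization=0.5):
    return CadreCost(
        cadre_id="nurse",
        annual_remuneration=remuneration,
        working_days_per_year=days,
        minutes_per_day=minutes,
        utilization=utilization,
    )


class TestServicesCount:
    @pytest.mark.parametrize(
        "pop, need, cov, expected",
        [
            (1_000_000, 0.20, 0.50, 100_000.0),
            (123_456, 0.77, 0.0, 0.0),
            (200_000, 1.5, 0.8, 240_000.0),  # need >1: multiple cases/year
            (0, 1.0, 1.0, 0.0),
        ],
    )
    def test_triple_product(self, pop, need, cov, expected):
        assert engine.services_count(pop, need, cov) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "pop, need, cov", [(-1, 0.5, 0.5), (100, -0.1, 0.5), (100, 0.5, 1.2), (100, 0.5, -0.1)]
    )
    def test_out_of_domain_rejected(self, pop, need, cov):
        with pytest.raises(DomainError):
            engine.services_count(pop, need, cov)


class TestCostPerMinute:
    def test_hand_arithmetic(self):
        # 12000 / (240 * 480 * 0.5) = 12000 / 57600
        assert engine.cost_per_minute(_cadre()) == pytest.approx(12_000 / 57_600)

    def test_identity_denominator(self):
        cadre = _cadre(remuneration=777.0, days=1, minutes=1, utilization=1.0)
        assert engine.cost_per_minute(cadre) == 777.0

    def test_zero_utilization_rejected_at_construction(self):
        with pytest.raises(ValueError):
            _cadre(utilization=0.0)


class TestDrugSupplyCost:
    def test_empty_is_zero(self):
        assert engine.drug_supply_cost_per_case([]) == 0.0

    @pytest.mark.parametrize(
        "lines, expected",
        [
            ([(0.05, 10, 1.0)], 0.50),
            ([(0.05, 10, 1.0), (2.00, 1, 0.5)], 1.50),
        ],
    )
    def test_hand_arithmetic(self, lines, expected):
        objs = [
            DrugSupplyLine(
                item_id=f"i{k}", unit_price=p, units_per_case=u, pct_receiving=f
            )
            for k, (p, u, f) in enumerate(lines)
        ]
        assert engine.drug_supply_cost_per_case(objs) == pytest.approx(expected)


class TestLaborCost:
    def test_single_cadre(self):
        lines = [ProviderTimeLine(cadre_id="nurse", minutes_per_visit=20, n_visits=3)]
        got = engine.labor_cost_per_case(lines, {"nurse": _cadre()})
        assert got == pytest.approx(12.50)

    def test_zero_visits(self):
        lines = [ProviderTimeLine(cadre_id="nurse", minutes_per_visit=20, n_visits=0)]
        assert engine.labor_cost_per_case(lines, {"nurse": _cadre()}) == 0.0

    def test_two_cadres_sum_independently(self):
        doctor = CadreCost(
            cadre_id="doctor",
            annual_remuneration=48_000.0,
            working_days_per_year=240.0,
            minutes_per_day=480.0,
            utilization=0.5,
        )
        cadres = {"nurse": _cadre(), "doctor": doctor}
        lines = [
            ProviderTimeLine(cadre_id="nurse", minutes_per_visit=20, n_visits=3),
            ProviderTimeLine(cadre_id="doctor", minutes_per_visit=10, n_visits=1),
        ]
        expected = sum(
            line.minutes_per_visit
            * line.n_visits
            * engine.cost_per_minute(cadres[line.cadre_id])
            for line in lines
        )
        assert engine.labor_cost_per_case(lines, cadres) == pytest.approx(expected)

    def test_unknown_cadre(self):
        lines = [ProviderTimeLine(cadre_id="ghost", minutes_per_visit=5, n_visits=1)]
        with pytest.raises(DomainError, match="ghost"):
            engine.labor_cost_per_case(lines, {"nurse": _cadre()})


class TestHotelOverhead:
    hotel = HotelCostTable(cost_per_opv=2.00, cost_per_ipd=10.00)
    hosp = DEFAULT_FACTOR_SHARES["hospital"]
    hc = DEFAULT_FACTOR_SHARES["health_centre"]

    def test_outpatient_uses_health_centre_shares(self):
        profile = VisitProfile(opv_per_case=4, ipd_per_case=0)
        od, ind = engine.hotel_overhead_per_case(profile, self.hotel, self.hosp, self.hc)
        assert od == pytest.approx(0.68)  # 8 x 0.085
        assert ind == pytest.approx(2.32)  # 8 x 0.290

    def test_inpatient_uses_hospital_shares(self):
        profile = VisitProfile(opv_per_case=0, ipd_per_case=1)
        od, ind = engine.hotel_overhead_per_case(profile, self.hotel, self.hosp, self.hc)
        assert od == pytest.approx(0.98)  # 10 x 0.098
        assert ind == pytest.approx(1.95)  # 10 x 0.195

    def test_zero_visits(self):
        profile = VisitProfile(opv_per_case=0, ipd_per_case=0)
        assert engine.hotel_overhead_per_case(
            profile, self.hotel, self.hosp, self.hc
        ) == (0.0, 0.0)


def _single_drug_channel(total, mix):
    return ChannelProfile(
        drug_lines=(
            DrugSupplyLine(
                item_id="x", unit_price=total, units_per_case=1, pct_receiving=1.0
            ),
        ),
        visit_profile=VisitProfile(opv_per_case=0, ipd_per_case=0),
        mix_fraction=mix,
    )


class TestUnitCostPerCase:
    def test_two_channel_mix_is_weighted_mean(self, mini_scenario):
        profile = InterventionProfile(
            intervention_id="x",
            channels={
                "a": _single_drug_channel(10.0, 0.5),
                "b": _single_drug_channel(20.0, 0.5),
            },
        )
        unit = engine.unit_cost_per_case(profile, mini_scenario.cost_db)
        assert unit.total == pytest.approx(15.0)

    def test_single_channel_equals_composition(self, mini_scenario):
        profile = mini_scenario.profiles["ors"]
        channel = profile.channels["facility"]
        unit = engine.unit_cost_per_case(profile, mini_scenario.cost_db)
        assert unit.drugs_supplies == pytest.approx(
            engine.drug_supply_cost_per_case(channel.drug_lines)
        )
        assert unit.labor == pytest.approx(
            engine.labor_cost_per_case(channel.time_lines, mini_scenario.cost_db.cadres)
        )
        od, ind = engine.hotel_overhead_per_case(
            channel.visit_profile,
            mini_scenario.cost_db.hotel,
            mini_scenario.cost_db.shares["hospital"],
            mini_scenario.cost_db.shares["health_centre"],
        )
        assert (unit.other_direct, unit.indirect) == pytest.approx((od, ind))

    def test_all_zero_inputs(self, mini_scenario):
        profile = InterventionProfile(
            intervention_id="z",
            channels={
                "only": ChannelProfile(
                    visit_profile=VisitProfile(opv_per_case=0, ipd_per_case=0),
                    mix_fraction=1.0,
                )
            },
        )
        unit = engine.unit_cost_per_case(profile, mini_scenario.cost_db)
        assert unit.total == 0.0


class TestInterventionCost:
    def test_drug_component_scales_with_services(self, mini_scenario):
        breakdown = engine.intervention_cost("ors", 2030, mini_scenario)
        assert breakdown.drugs_supplies == pytest.approx(50_000.0)  # 100k x 0.50
        assert breakdown.labor == pytest.approx(1_250_000.0)  # 100k x 12.50
        assert breakdown.other_direct == pytest.approx(68_000.0)
        assert breakdown.indirect == pytest.approx(232_000.0)
        assert breakdown.above_facility == 0.0

    def test_zero_coverage_gives_zero_breakdown(self, mini_scenario):
        scenario = mini_scenario.model_copy(
            update={
                "needs": tuple(
                    r.model_copy(update={"coverage_fraction": 0.0})
                    for r in mini_scenario.needs
                )
            }
        )
        assert engine.intervention_cost("ors", 2030, scenario).total == 0.0

    def test_unknown_intervention_and_year(self, mini_scenario):
        with pytest.raises(DomainError):
            engine.intervention_cost("nope", 2030, mini_scenario)
        with pytest.raises(DomainError):
            engine.intervention_cost("ors", 1999, mini_scenario)


class TestProgramCosts:
    def test_all_zero(self):
        spec = ProgramCostSpec(
            items={
                "research": ProgramCostItem(fixed_amount=0.0),
                "program_management": ProgramCostItem(markup_fraction=0.0),
            }
        )
        assert engine.program_costs(spec, 5e6).total == 0.0

    def test_markup(self):
        spec = ProgramCostSpec(
            items={"program_management": ProgramCostItem(markup_fraction=0.10)}
        )
        assert engine.program_costs(spec, 1_000_000.0).total == pytest.approx(100_000.0)

    def test_mixed_amount_and_markup(self):
        spec = ProgramCostSpec(
            items={
                "training_above_facility": ProgramCostItem(fixed_amount=50_000.0),
                "monitoring_evaluation": ProgramCostItem(markup_fraction=0.02),
            }
        )
        result = engine.program_costs(spec, 1_000_000.0)
        assert result.total == pytest.approx(70_000.0)
        assert result.by_category["monitoring_evaluation"] == pytest.approx(20_000.0)

    def test_negative_facility_total_rejected(self):
        with pytest.raises(DomainError):
            engine.program_costs(ProgramCostSpec(), -1.0)


class TestTotalCost:
    def test_single_intervention_with_markup(self, mini_scenario):
        iv = engine.intervention_cost("ors", 2030, mini_scenario)
        total = engine.total_cost(mini_scenario, 2030)
        assert total.above_facility == pytest.approx(0.10 * iv.total)
        assert total.total == pytest.approx(1.10 * iv.total)

    def test_zero_program_costs_reduce_to_intervention(self, mini_scenario):
        scenario = mini_scenario.model_copy(
            update={"program_costs": ProgramCostSpec()}
        )
        iv = engine.intervention_cost("ors", 2030, scenario)
        total = engine.total_cost(scenario, 2030)
        assert total.as_dict() == pytest.approx(iv.as_dict())

    def test_matches_brute_force_on_fixture(self, toy_scenario):
        for year in toy_scenario.years:
            oracle = brute_force_costs(toy_scenario, year)
            got = engine.total_cost(toy_scenario, year).as_dict()
            for component, expected in oracle.items():
                assert got[component] == pytest.approx(expected, rel=1e-9)


class TestNoDoubleCounting:
    def test_personnel_and_consumables_shares_are_inert(self, mini_scenario):
        """Only the other-direct and indirect shares may influence costing."""
        baseline = engine.total_cost(mini_scenario, 2030)
        twisted_shares = {
            lvl: FactorShares(
                level=lvl,
                s_personnel=s.s_consumables,  # swap the two inert shares
                s_consumables=s.s_personnel,
                s_odc=s.s_odc,
                s_indirect=s.s_indirect,
            )
            for lvl, s in mini_scenario.cost_db.shares.items()
        }
        scenario = mini_scenario.model_copy(
            update={
                "cost_db": UnitCostDB(
                    cadres=mini_scenario.cost_db.cadres,
                    hotel=mini_scenario.cost_db.hotel,
                    shares=twisted_shares,
                )
            }
        )
        assert engine.total_cost(scenario, 2030).as_dict() == baseline.as_dict()


def test_scenario_costs_table_shape(mini_scenario):
    df = engine.scenario_costs(mini_scenario, include_totals=False)
    assert len(df) == 6  # five components + total for 1 intervention x 1 year
    with_totals = engine.scenario_costs(mini_scenario)
    assert len(with_totals) == 12
    totals = with_totals[with_totals["intervention_id"] == engine.TOTAL_ROW_ID]
    by_comp = totals.set_index("component")["usd"]
    comps = ["drugs_supplies", "labor", "other_direct", "indirect", "above_facility"]
    assert by_comp["total"] == pytest.approx(sum(by_comp[c] for c in comps), rel=1e-12)
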