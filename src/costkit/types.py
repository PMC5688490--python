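"""Domain types for intervention costing scenarios.

The container hierarchy mirrors how a costing exercise is set up in practice:
target populations by year, the fraction of each population in need of an
intervention and the effective coverage reached, per-case treatment inputs
(drug/supply ingredient lines, provider minutes, outpatient visits and
inpatient bed-days), the price side (cadre remuneration, hotel costs per
visit/bed-day, factor-share proportions), and an above-facility program-cost
specification. A :class:`Scenario` bundles all of it for one projection.

All fractions are stored as proportions in ``[0, 1]`` (readers can convert a
percent dialect); the one deliberate exception is ``need_fraction``, which may
exceed 1 to express more than one case per person-year (e.g. diarrhoea or
malaria episodes).
"""

from __future__ import annotations

from typing import Dict, Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ScenarioValidationError

#: Facility levels; hospital shares apply to inpatient days, health-centre
#: shares to outpatient visits.
LEVELS: Tuple[str, ...] = ("hospital", "health_centre")

Level = Literal["hospital", "health_centre"]

#: The six above-facility program-cost categories.
PROGRAM_COST_CATEGORIES: Tuple[str, ...] = (
    "program_management",
    "research",
    "monitoring_evaluation",
    "communication_media_outreach",
    "training_above_facility",
    "infrastructure_equipment",
)

#: Facility-level cost components plus the above-facility block, in report order.
COMPONENTS: Tuple[str, ...] = (
    "drugs_supplies",
    "labor",
    "other_direct",
    "indirect",
    "above_facility",
)


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class TargetPopulation(_Frozen):
    """One population group (e.g. pregnant women) in one calendar year."""

    pop_id: str
    year: int
    count: float = Field(ge=0, description="persons")


class NeedCoverage(_Frozen):
    """Need and effective coverage linking an intervention to a population-year.

    ``need_fraction`` may exceed 1 where a person can require the service more
    than once a year; ``coverage_fraction`` is the share of those in need who
    are actually served and is bounded by 1.
    """

    intervention_id: str
    pop_id: str
    year: int
    need_fraction: float = Field(ge=0)
    coverage_fraction: float = Field(ge=0, le=1)


class DrugSupplyLine(_Frozen):
    """One ingredient line: a drug or consumable supply item per case treated."""

    item_id: str
    unit_price: float = Field(ge=0, description="USD per unit")
    units_per_case: float = Field(ge=0)
    pct_receiving: float = Field(ge=0, le=1)


class ProviderTimeLine(_Frozen):
    """Provider time of one cadre: minutes per visit times number of visits."""

    cadre_id: str
    minutes_per_visit: float = Field(ge=0)
    n_visits: float = Field(ge=0)


class CadreCost(_Frozen):
    """Remuneration and time budget of one health-worker cadre.

    ``utilization`` is the productive fraction of paid time; it enters the
    denominator of the cost per minute, so lower utilization makes each
    delivered minute more expensive.
    """

    cadre_id: str
    annual_remuneration: float = Field(ge=0, description="USD/year, wages + benefits")
    working_days_per_year: float = Field(gt=0)
    minutes_per_day: float = Field(gt=0)
    utilization: float = Field(gt=0, le=1)


class VisitProfile(_Frozen):
    """Outpatient visits and inpatient bed-days required per case."""

    opv_per_case: float = Field(ge=0)
    ipd_per_case: float = Field(ge=0)


class HotelCostTable(_Frozen):
    """Country 'hotel' cost of one outpatient visit and one inpatient bed-day.

    The hotel cost bundles everything except drugs and laboratory costs:
    personnel, consumables, other-direct and indirect components.
    """

    cost_per_opv: float = Field(ge=0, description="USD per outpatient visit")
    cost_per_ipd: float = Field(ge=0, description="USD per inpatient bed-day")


class FactorShares(_Frozen):
    """Proportions of the unit cost attributable to each of four factors.

    The four factors decompose a facility's unit cost: personnel, consumables
    (excluding drugs and laboratory costs), other direct costs (nonconsumables
    and facility-level training) and indirect costs (capital, support
    personnel, maintenance/utilities, supervision/management). Only the
    other-direct and indirect shares are consumed by the costing engine — the
    personnel and consumables portions of the hotel cost are already
    ingredient-costed, and adding them again would double count.

    Rows are allowed to sum to slightly less than 1 because the packaged
    health-centre defaults, kept verbatim as published, sum to 0.969.
    """

    level: Level
    s_personnel: float = Field(ge=0, le=1)
    s_consumables: float = Field(ge=0, le=1)
    s_odc: float = Field(ge=0, le=1)
    s_indirect: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _check_sum(self) -> "FactorShares":
        total = self.s_personnel + self.s_consumables + self.s_odc + self.s_indirect
        if not (0.95 <= total <= 1.01):
            raise ValueError(
                f"factor shares for level {self.level!r} sum to {total:.4f}, "
                "expected a value in [0.95, 1.01]"
            )
        return self

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.s_personnel, self.s_consumables, self.s_odc, self.s_indirect)


class ChannelProfile(_Frozen):
    """Treatment inputs for one delivery channel of an intervention."""

    drug_lines: Tuple[DrugSupplyLine, ...] = ()
    time_lines: Tuple[ProviderTimeLine, ...] = ()
    visit_profile: VisitProfile = VisitProfile(opv_per_case=0.0, ipd_per_case=0.0)
    mix_fraction: float = Field(ge=0, le=1)


class InterventionProfile(_Frozen):
    """Per-case treatment inputs for one intervention, by delivery channel.

    Channel mix fractions are constant over the projection period and must
    sum to 1.
    """

    intervention_id: str
    channels: Dict[str, ChannelProfile]

    @model_validator(mode="after")
    def _check_channels(self) -> "InterventionProfile":
        if not self.channels:
            raise ValueError(
                f"intervention {self.intervention_id!r} has no delivery channel"
            )
        total = sum(c.mix_fraction for c in self.channels.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"intervention {self.intervention_id!r}: channel mix fractions "
                f"sum to {total!r}, expected 1"
            )
        return self


class ProgramCostItem(_Frozen):
    """Above-facility cost for one category: a fixed annual amount, or a
    markup fraction applied to the total facility-level cost. Exactly one of
    the two must be given."""

    fixed_amount: Optional[float] = Field(default=None, ge=0)
    markup_fraction: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_exclusive(self) -> "ProgramCostItem":
        if (self.fixed_amount is None) == (self.markup_fraction is None):
            raise ValueError(
                "exactly one of fixed_amount or markup_fraction must be set"
            )
        return self


class ProgramCostSpec(_Frozen):
    """Above-facility program costs per category.

    Categories not listed contribute nothing. Unknown category names are
    rejected.
    """

    items: Dict[str, ProgramCostItem] = {}

    @model_validator(mode="after")
    def _check_categories(self) -> "ProgramCostSpec":
        unknown = set(self.items) - set(PROGRAM_COST_CATEGORIES)
        if unknown:
            raise ValueError(
                f"unknown program-cost categories: {sorted(unknown)}; "
                f"expected a subset of {list(PROGRAM_COST_CATEGORIES)}"
            )
        return self


class UnitCostPerCase(_Frozen):
    """Facility-level cost of treating one case, by component (USD/case)."""

    drugs_supplies: float = Field(ge=0)
    labor: float = Field(ge=0)
    other_direct: float = Field(ge=0)
    indirect: float = Field(ge=0)

    @property
    def total(self) -> float:
        return self.drugs_supplies + self.labor + self.other_direct + self.indirect


class CostBreakdown(_Frozen):
    """A cost total disaggregated into its five components (USD).

    ``total`` must equal the component sum to 1e-9 relative tolerance; use
    :meth:`from_components` to build one safely.
    """

    drugs_supplies: float = Field(ge=0)
    labor: float = Field(ge=0)
    other_direct: float = Field(ge=0)
    indirect: float = Field(ge=0)
    above_facility: float = Field(ge=0)
    total: float = Field(ge=0)

    @model_validator(mode="after")
    def _check_total(self) -> "CostBreakdown":
        s = (
            self.drugs_supplies
            + self.labor
            + self.other_direct
            + self.indirect
            + self.above_facility
        )
        if abs(self.total - s) > 1e-9 * max(1.0, abs(s)):
            raise ValueError(
                f"total {self.total!r} does not equal component sum {s!r}"
            )
        return self

    @classmethod
    def from_components(
        cls,
        drugs_supplies: float = 0.0,
        labor: float = 0.0,
        other_direct: float = 0.0,
        indirect: float = 0.0,
        above_facility: float = 0.0,
    ) -> "CostBreakdown":
        return cls(
            drugs_supplies=drugs_supplies,
            labor=labor,
            other_direct=other_direct,
            indirect=indirect,
            above_facility=above_facility,
            total=drugs_supplies + labor + other_direct + indirect + above_facility,
        )

    @classmethod
    def zero(cls) -> "CostBreakdown":
        return cls.from_components()

    def __add__(self, other: "CostBreakdown") -> "CostBreakdown":
        return CostBreakdown.from_components(
            drugs_supplies=self.drugs_supplies + other.drugs_supplies,
            labor=self.labor + other.labor,
            other_direct=self.other_direct + other.other_direct,
            indirect=self.indirect + other.indirect,
            above_facility=self.above_facility + other.above_facility,
        )

    def as_dict(self) -> Dict[str, float]:
        return {
            "drugs_supplies": self.drugs_supplies,
            "labor": self.labor,
            "other_direct": self.other_direct,
            "indirect": self.indirect,
            "above_facility": self.above_facility,
            "total": self.total,
        }


class UnitCostDB(_Frozen):
    """Price side of a scenario: cadre costs, hotel costs and factor shares."""

    cadres: Dict[str, CadreCost]
    hotel: HotelCostTable
    shares: Dict[str, FactorShares]

    @model_validator(mode="after")
    def _check_levels(self) -> "UnitCostDB":
        missing = set(LEVELS) - set(self.shares)
        if missing:
            raise ValueError(f"factor shares missing for levels: {sorted(missing)}")
        for cadre_id, cadre in self.cadres.items():
            if cadre.cadre_id != cadre_id:
                raise ValueError(
                    f"cadre key {cadre_id!r} does not match record id "
                    f"{cadre.cadre_id!r}"
                )
        return self


class FacilityCostRecord(_Frozen):
    """One facility-year of cost data for the factor-share estimation.

    ``total_cost`` is the sum of the four factor expenditures; prices are per
    factor unit. The optional ``share_*`` fields carry observed expenditure
    shares (personnel, consumables, other-direct; the indirect share is the
    complement) and are needed only by the share-system estimator.
    """

    facility_id: str
    level: Level
    total_cost: float = Field(gt=0)
    price_personnel: float = Field(gt=0)
    price_consumables: float = Field(gt=0)
    price_odc: float = Field(gt=0)
    price_indirect: float = Field(gt=0)
    output_volume: float = Field(gt=0, description="services/year")
    share_personnel: Optional[float] = None
    share_consumables: Optional[float] = None
    share_odc: Optional[float] = None
    share_indirect: Optional[float] = None


class Scenario(BaseModel):
    """A complete costing scenario over an inclusive year range.

    Construction validates referential integrity: every intervention that
    appears in the need/coverage table has a treatment-input profile, every
    cadre referenced by a time line has a cost record, and every need row
    points at an existing population-year.
    """

    model_config = ConfigDict(extra="forbid")

    name: str
    year_range: Tuple[int, int]
    populations: Tuple[TargetPopulation, ...]
    needs: Tuple[NeedCoverage, ...]
    profiles: Dict[str, InterventionProfile]
    cost_db: UnitCostDB
    program_costs: ProgramCostSpec = ProgramCostSpec()

    @model_validator(mode="after")
    def _validate_refs(self) -> "Scenario":
        start, end = self.year_range
        if start > end:
            raise ValueError(f"year_range start {start} after end {end}")

        seen_pop = set()
        for p in self.populations:
            key = (p.pop_id, p.year)
            if key in seen_pop:
                raise ValueError(f"duplicate population row for {key}")
            seen_pop.add(key)

        seen_need = set()
        for r in self.needs:
            key = (r.intervention_id, r.pop_id, r.year)
            if key in seen_need:
                raise ValueError(f"duplicate need row for {key}")
            seen_need.add(key)
            if r.intervention_id not in self.profiles:
                raise ValueError(
                    f"need row {key}: intervention {r.intervention_id!r} has no "
                    "treatment-input profile"
                )
            if (r.pop_id, r.year) not in seen_pop:
                raise ValueError(
                    f"need row {key}: population {(r.pop_id, r.year)} not found"
                )

        for iv_id, profile in self.profiles.items():
            if profile.intervention_id != iv_id:
                raise ValueError(
                    f"profile key {iv_id!r} does not match record id "
                    f"{profile.intervention_id!r}"
                )
            for ch_name, channel in profile.channels.items():
                for line in channel.time_lines:
                    if line.cadre_id not in self.cost_db.cadres:
                        raise ValueError(
                            f"intervention {iv_id!r} channel {ch_name!r}: unknown "
                            f"cadre {line.cadre_id!r}"
                        )
        return self

    # -- lookups -----------------------------------------------------------

    @property
    def years(self) -> range:
        return range(self.year_range[0], self.year_range[1] + 1)

    @property
    def interventions(self) -> Tuple[str, ...]:
        return tuple(sorted(self.profiles))

    def population_count(self, pop_id: str, year: int) -> float:
        for p in self.populations:
            if p.pop_id == pop_id and p.year == year:
                return p.count
        raise ScenarioValidationError(f"no population row for {(pop_id, year)}")

    def needs_for(self, intervention_id: str, year: int) -> Tuple[NeedCoverage, ...]:
        return tuple(
            r
            for r in self.needs
            if r.intervention_id == intervention_id and r.year == year
        )
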