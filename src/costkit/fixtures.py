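"""Synthetic input generators.

Two generators make the whole package testable without any external
databases:

* :func:`build_country_scenario` / :func:`generate_country_fixture` — a toy
  country: target populations, need and coverage trajectories, per-case
  treatment-input profiles (with one or two delivery channels), cadre costs,
  hotel costs, the packaged default factor shares and a nonzero
  above-facility program-cost specification. It emulates the *structure* of
  the intervention databases a country application would draw on, not any
  real country's epidemiology.

* :func:`simulate_facility_costs` — facility-level cost records drawn from a
  known translog data-generating process, for exercising and validating the
  factor-share estimator. Log prices are i.i.d. uniform on [-0.5, 0.5]
  (so the translog is well conditioned around prices of 1 and expected log
  normalized prices are zero, making the mean factor shares equal the
  first-order coefficients), output is lognormal, and noise is multiplicative
  lognormal on cost (cost data are positive and right-skewed).

Both are deterministic: the same seed gives byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .defaults import DEFAULT_FACTOR_SHARES
from .errors import ScenarioValidationError
from .io import write_facilities, write_scenario
from .types import (
    CadreCost,
    ChannelProfile,
    DrugSupplyLine,
    FactorShares,
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

#: Default symmetric second-order terms: small but nonzero, so the
#: cost-function and share-system estimators are distinguishable.
DEFAULT_GAMMA = np.array(
    [
        [0.02, -0.01, -0.01],
        [-0.01, 0.02, -0.01],
        [-0.01, -0.01, 0.02],
    ]
)


def _default_true_shares() -> Dict[str, Tuple[float, float, float, float]]:
    """DGP truth per level: the packaged hospital row (sums to 1.000) and the
    health-centre row renormalized to sum to 1 (as printed it sums to 0.969,
    but a data-generating process needs exact adding-up)."""
    hosp = DEFAULT_FACTOR_SHARES["hospital"].as_tuple()
    hc = np.array(DEFAULT_FACTOR_SHARES["health_centre"].as_tuple())
    hc = tuple(hc / hc.sum())
    return {"hospital": hosp, "health_centre": hc}


@dataclass
class FixtureConfig:
    """Configuration for the synthetic generators.

    ``true_shares`` are the DGP factor shares per facility level and must sum
    to 1; ``noise_sd`` is the standard deviation of the log-scale cost noise.
    """

    seed: int = 42
    n_interventions: int = 10
    n_cadres: int = 3
    year_range: Tuple[int, int] = (2025, 2030)
    n_facilities: Mapping[str, int] = field(
        default_factory=lambda: {"hospital": 500, "health_centre": 500}
    )
    true_shares: Mapping[str, Tuple[float, float, float, float]] = field(
        default_factory=_default_true_shares
    )
    noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_interventions < 1 or self.n_cadres < 1:
            raise ScenarioValidationError(
                "n_interventions and n_cadres must be at least 1"
            )
        if self.year_range[0] > self.year_range[1]:
            raise ScenarioValidationError(f"invalid year_range {self.year_range}")
        if self.noise_sd < 0:
            raise ScenarioValidationError("noise_sd must be >= 0")
        for lvl, shares in self.true_shares.items():
            if abs(sum(shares) - 1.0) > 1e-9:
                raise ScenarioValidationError(
                    f"true_shares[{lvl!r}] sum to {sum(shares)!r}, expected 1"
                )


# ---------------------------------------------------------------------------
# toy-country scenario
# ---------------------------------------------------------------------------

_POP_NAMES = ("pregnant_women", "births", "children_1_11m", "children_12_59m")
_CHANNEL_NAMES = ("facility", "outreach")


def build_country_scenario(config: Optional[FixtureConfig] = None) -> Scenario:
    """Build the toy-country scenario in memory (deterministic under seed)."""
    config = config or FixtureConfig()
    rng = np.random.default_rng(config.seed)
    y0, y1 = config.year_range
    years = list(range(y0, y1 + 1))

    cadre_ids = [f"cadre_{i + 1:02d}" for i in range(config.n_cadres)]
    cadres = {
        cid: CadreCost(
            cadre_id=cid,
            annual_remuneration=round(float(rng.uniform(3_000, 30_000)), 2),
            working_days_per_year=230.0,
            minutes_per_day=480.0,
            utilization=round(float(rng.uniform(0.4, 0.9)), 2),
        )
        for cid in cadre_ids
    }

    pops = []
    pop_ids = list(_POP_NAMES)
    for pid in pop_ids:
        base = float(rng.uniform(5e4, 2e6))
        for year in years:
            pops.append(
                TargetPopulation(
                    pop_id=pid,
                    year=year,
                    count=round(base * 1.01 ** (year - y0), 1),
                )
            )

    needs = []
    profiles: Dict[str, InterventionProfile] = {}
    for i in range(config.n_interventions):
        iv = f"int_{i + 1:02d}"
        pid = pop_ids[int(rng.integers(0, len(pop_ids)))]
        need = round(float(rng.uniform(0.05, 1.5)), 3)
        cov0 = float(rng.uniform(0.1, 0.5))
        cov1 = float(rng.uniform(cov0, 0.95))
        for year in years:
            frac = (year - y0) / max(1, y1 - y0)
            needs.append(
                NeedCoverage(
                    intervention_id=iv,
                    pop_id=pid,
                    year=year,
                    need_fraction=need,
                    coverage_fraction=round(cov0 + frac * (cov1 - cov0), 4),
                )
            )

        n_channels = int(rng.integers(1, 3))
        if n_channels == 2:
            f = round(float(rng.uniform(0.3, 0.7)), 2)
            mix = {"facility": f, "outreach": round(1.0 - f, 2)}
        else:
            mix = {"facility": 1.0}
        channels = {}
        for ch_name, mix_frac in mix.items():
            drug_lines = tuple(
                DrugSupplyLine(
                    item_id=f"item_{i + 1:02d}_{ch_name[:1]}{j + 1}",
                    unit_price=round(float(rng.uniform(0.05, 20.0)), 2),
                    units_per_case=float(rng.integers(1, 31)),
                    pct_receiving=round(float(rng.uniform(0.5, 1.0)), 2),
                )
                for j in range(int(rng.integers(1, 5)))
            )
            used = rng.choice(
                cadre_ids, size=int(rng.integers(1, len(cadre_ids) + 1)), replace=False
            )
            time_lines = tuple(
                ProviderTimeLine(
                    cadre_id=str(cid),
                    minutes_per_visit=round(float(rng.uniform(5, 60)), 1),
                    n_visits=float(rng.integers(1, 5)),
                )
                for cid in sorted(used)
            )
            ipd = 0.0 if rng.uniform() < 0.7 else round(float(rng.uniform(0.5, 3.0)), 1)
            channels[ch_name] = ChannelProfile(
                drug_lines=drug_lines,
                time_lines=time_lines,
                visit_profile=VisitProfile(
                    opv_per_case=round(float(rng.uniform(0.5, 4.0)), 1),
                    ipd_per_case=ipd,
                ),
                mix_fraction=mix_frac,
            )
        profiles[iv] = InterventionProfile(intervention_id=iv, channels=channels)

    hotel = HotelCostTable(
        cost_per_opv=round(float(rng.uniform(1.0, 5.0)), 2),
        cost_per_ipd=round(float(rng.uniform(5.0, 25.0)), 2),
    )
    program_costs = ProgramCostSpec(
        items={
            "program_management": ProgramCostItem(markup_fraction=0.10),
            "monitoring_evaluation": ProgramCostItem(markup_fraction=0.03),
            "communication_media_outreach": ProgramCostItem(markup_fraction=0.02),
            "research": ProgramCostItem(fixed_amount=20_000.0),
            "training_above_facility": ProgramCostItem(fixed_amount=50_000.0),
            "infrastructure_equipment": ProgramCostItem(fixed_amount=100_000.0),
        }
    )
    return Scenario(
        name=f"toy_country_seed{config.seed}",
        year_range=config.year_range,
        populations=tuple(pops),
        needs=tuple(needs),
        profiles=profiles,
        cost_db=UnitCostDB(
            cadres=cadres, hotel=hotel, shares=dict(DEFAULT_FACTOR_SHARES)
        ),
        program_costs=program_costs,
    )


def generate_country_fixture(
    config: Optional[FixtureConfig] = None,
    out_dir: Union[str, Path] = "fixture_country",
) -> Path:
    """Write the complete toy-country file set; returns the scenario.json path.

    Also writes ``facilities.csv`` with the synthetic facility-cost dataset
    for both levels. Identical seeds give byte-identical files.
    """
    config = config or FixtureConfig()
    out_dir = Path(out_dir)
    scenario = build_country_scenario(config)
    json_path = write_scenario(scenario, out_dir)
    frames = []
    for lvl_idx, lvl in enumerate(("hospital", "health_centre")):
        frames.append(
            simulate_facility_costs(
                n_facilities=config.n_facilities[lvl],
                true_shares=config.true_shares[lvl],
                seed=config.seed + 1000 * (lvl_idx + 1),
                noise_sd=config.noise_sd,
                level=lvl,
            )
        )
    write_facilities(pd.concat(frames, ignore_index=True), out_dir / "facilities.csv")
    return json_path


# ---------------------------------------------------------------------------
# facility-cost DGP
# ---------------------------------------------------------------------------


def simulate_facility_costs(
    n_facilities: int = 500,
    true_shares: Sequence[float] = (0.390, 0.317, 0.098, 0.195),
    seed: int = 0,
    noise_sd: float = 0.05,
    level: str = "hospital",
    gamma: Optional[np.ndarray] = None,
    delta_y: float = 1.0,
    beta0: float = 1.0,
    output_log_mean: float = np.log(5_000.0),
    output_log_sd: float = 0.5,
    share_noise_sd: float = 0.01,
) -> pd.DataFrame:
    """Facility-cost records from a translog data-generating process.

    The first-order coefficients equal ``true_shares[:3]`` so that, with log
    prices centred at zero, the expected factor shares at the mean evaluation
    point equal ``true_shares``. ``gamma`` is the symmetric 3x3 second-order
    block in the normalized parameterization (defaults to small +-0.01/0.02
    terms); pass zeros for a Cobb-Douglas process. Observed expenditure
    shares (Shephard shares plus N(0, share_noise_sd) noise) are included for
    the share-system estimator.
    """
    true_shares = np.asarray(true_shares, dtype=float)
    if true_shares.shape != (4,) or abs(true_shares.sum() - 1.0) > 1e-9:
        raise ScenarioValidationError(
            f"true_shares must be 4 values summing to 1, got {true_shares!r}"
        )
    if noise_sd < 0:
        raise ScenarioValidationError("noise_sd must be >= 0")
    G = DEFAULT_GAMMA if gamma is None else np.asarray(gamma, dtype=float)
    if G.shape != (3, 3) or not np.allclose(G, G.T):
        raise ScenarioValidationError("gamma must be a symmetric 3x3 matrix")

    rng = np.random.default_rng(seed)
    lnp = rng.uniform(-0.5, 0.5, size=(n_facilities, 4))
    lny = rng.normal(output_log_mean, output_log_sd, size=n_facilities)
    noise = rng.normal(0.0, noise_sd, size=n_facilities) if noise_sd > 0 else 0.0

    z = lnp[:, :3] - lnp[:, 3:4]
    beta = true_shares[:3]
    ln_c_norm = (
        beta0
        + z @ beta
        + 0.5 * np.einsum("ni,ij,nj->n", z, G, z)
        + delta_y * lny
        + noise
    )
    ln_total_cost = ln_c_norm + lnp[:, 3]

    shares_true = beta[None, :] + z @ G.T  # s_i = beta_i + sum_j G_ij z_j
    share_noise = rng.normal(0.0, share_noise_sd, size=(n_facilities, 3))
    shares_obs = shares_true + share_noise

    prices = np.exp(lnp)
    return pd.DataFrame(
        {
            "facility_id": [
                f"{level[:4]}_{i + 1:04d}" for i in range(n_facilities)
            ],
            "level": level,
            "total_cost": np.exp(ln_total_cost),
            "price_personnel": prices[:, 0],
            "price_consumables": prices[:, 1],
            "price_odc": prices[:, 2],
            "price_indirect": prices[:, 3],
            "output_volume": np.exp(lny),
            "share_personnel": shares_obs[:, 0],
            "share_consumables": shares_obs[:, 1],
            "share_odc": shares_obs[:, 2],
            "share_indirect": 1.0 - shares_obs.sum(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# small random scenarios for oracle tests
# ---------------------------------------------------------------------------


def random_small_scenario(
    seed: int, max_interventions: int = 5
) -> Scenario:
    """A small random but valid scenario (<= ``max_interventions``), for
    brute-force oracle comparisons."""
    rng = np.random.default_rng(seed)
    config = FixtureConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_interventions=int(rng.integers(1, max_interventions + 1)),
        n_cadres=int(rng.integers(1, 4)),
        year_range=(2025, 2025 + int(rng.integers(0, 3))),
    )
    return build_country_scenario(config)
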