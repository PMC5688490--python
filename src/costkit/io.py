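"""Readers and writers for scenario configuration tables and result exports.

All tables are UTF-8 CSV with a header row and ``.`` decimal separator. A
scenario is described by a ``scenario.json`` file holding the name, the year
range, pointers to the component CSV files (relative paths are resolved
against the JSON file's directory), the channel mix per intervention and the
above-facility program-cost specification.

Fraction-valued columns are stored as proportions; pass ``percent=True`` to
the readers to accept tables written in percent (values are divided by 100).

Every reader validates row-by-row and raises
:class:`~costkit.errors.ScenarioValidationError` naming the file and the
offending row; malformed input never produces a silent default.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
import pydantic

from .errors import ScenarioValidationError
from .types import (
    COMPONENTS,
    LEVELS,
    CadreCost,
    ChannelProfile,
    DrugSupplyLine,
    FacilityCostRecord,
    FactorShares,
    HotelCostTable,
    InterventionProfile,
    NeedCoverage,
    ProgramCostItem,
    ProgramCostSpec,
    ProviderTimeLine,
    Scenario,
    TargetPopulation,
    VisitProfile,
)

PathLike = Union[str, Path]

#: Component labels used in results.csv exports. Facility other-direct costs
#: are reported as "other_recurrent" and indirect costs as "capital",
#: following the conventional labelling of costing outputs.
EXPORT_LABELS = {
    "drugs_supplies": "drugs_supplies",
    "labor": "labor",
    "other_direct": "other_recurrent",
    "indirect": "capital",
    "above_facility": "above_facility",
    "total": "total",
}
_IMPORT_LABELS = {v: k for k, v in EXPORT_LABELS.items()}

_RESULTS_HEADER_NOTE = (
    "# costkit results export\n"
    "# component mapping: other_recurrent = facility other-direct costs; "
    "capital = facility indirect costs\n"
)


def _read_csv(path: PathLike, **kwargs) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ScenarioValidationError(f"missing input file: {path}")
    try:
        return pd.read_csv(path, comment="#", float_precision="round_trip", **kwargs)
    except Exception as exc:  # malformed CSV
        raise ScenarioValidationError(f"{path}: cannot parse CSV ({exc})") from exc


def _rows_to_models(df: pd.DataFrame, model_cls, path: PathLike) -> List:
    out = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        try:
            out.append(model_cls(**row))
        except pydantic.ValidationError as exc:
            first = exc.errors()[0]
            field = ".".join(str(p) for p in first["loc"]) or "<row>"
            raise ScenarioValidationError(
                f"{path}, row {idx + 2}: field {field!r}: {first['msg']} "
                f"(value {row.get(field, row)!r})"
            ) from exc
    return out


def _to_csv(df: pd.DataFrame, path: PathLike) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# per-table readers/writers
# ---------------------------------------------------------------------------


def read_populations(path: PathLike) -> List[TargetPopulation]:
    df = _read_csv(path)
    return _rows_to_models(df, TargetPopulation, path)


def write_populations(rows: Iterable[TargetPopulation], path: PathLike) -> None:
    _to_csv(pd.DataFrame([r.model_dump() for r in rows]), path)


def read_needs(path: PathLike, percent: bool = False) -> List[NeedCoverage]:
    df = _read_csv(path)
    if percent:
        for col in ("need_fraction", "coverage_fraction"):
            if col in df.columns:
                df[col] = df[col] / 100.0
    return _rows_to_models(df, NeedCoverage, path)


def write_needs(rows: Iterable[NeedCoverage], path: PathLike) -> None:
    _to_csv(pd.DataFrame([r.model_dump() for r in rows]), path)


def read_cadres(path: PathLike) -> Dict[str, CadreCost]:
    rows = _rows_to_models(_read_csv(path), CadreCost, path)
    return {r.cadre_id: r for r in rows}


def write_cadres(cadres: Mapping[str, CadreCost], path: PathLike) -> None:
    _to_csv(pd.DataFrame([c.model_dump() for c in cadres.values()]), path)


def read_hotel_costs(path: PathLike) -> HotelCostTable:
    rows = _rows_to_models(_read_csv(path), HotelCostTable, path)
    if len(rows) != 1:
        raise ScenarioValidationError(
            f"{path}: expected exactly one hotel-cost row, found {len(rows)}"
        )
    return rows[0]


def write_hotel_costs(hotel: HotelCostTable, path: PathLike) -> None:
    _to_csv(pd.DataFrame([hotel.model_dump()]), path)


def read_shares(path: PathLike, percent: bool = False) -> Dict[str, FactorShares]:
    df = _read_csv(path)
    if percent:
        for col in ("s_personnel", "s_consumables", "s_odc", "s_indirect"):
            if col in df.columns:
                df[col] = df[col] / 100.0
    rows = _rows_to_models(df, FactorShares, path)
    out = {r.level: r for r in rows}
    if len(out) != len(rows):
        raise ScenarioValidationError(f"{path}: duplicate factor-share level")
    return out


def write_shares(shares: Mapping[str, FactorShares], path: PathLike) -> None:
    _to_csv(
        pd.DataFrame([shares[lvl].model_dump() for lvl in LEVELS if lvl in shares]),
        path,
    )


class _DrugRow(pydantic.BaseModel):
    intervention_id: str
    channel: str
    item_id: str
    unit_price: float
    units_per_case: float
    pct_receiving: float


class _TimeRow(pydantic.BaseModel):
    intervention_id: str
    channel: str
    cadre_id: str
    minutes_per_visit: float
    n_visits: float


class _VisitRow(pydantic.BaseModel):
    intervention_id: str
    channel: str
    opv_per_case: float
    ipd_per_case: float


def read_profiles(
    drug_path: PathLike,
    time_path: PathLike,
    visits_path: PathLike,
    channel_mix: Mapping[str, Mapping[str, float]],
    percent: bool = False,
) -> Dict[str, InterventionProfile]:
    """Assemble intervention profiles from the three flat treatment-input
    tables plus the channel-mix mapping from scenario.json."""
    drug_df = _read_csv(drug_path)
    if percent and "pct_receiving" in drug_df.columns:
        drug_df["pct_receiving"] = drug_df["pct_receiving"] / 100.0
    drug_rows = _rows_to_models(drug_df, _DrugRow, drug_path)
    time_rows = _rows_to_models(_read_csv(time_path), _TimeRow, time_path)
    visit_rows = _rows_to_models(_read_csv(visits_path), _VisitRow, visits_path)

    channels: Dict[str, Dict[str, dict]] = {}

    def _channel(iv: str, ch: str) -> dict:
        return channels.setdefault(iv, {}).setdefault(
            ch, {"drug_lines": [], "time_lines": [], "visit_profile": None}
        )

    for r in drug_rows:
        try:
            line = DrugSupplyLine(
                item_id=r.item_id,
                unit_price=r.unit_price,
                units_per_case=r.units_per_case,
                pct_receiving=r.pct_receiving,
            )
        except pydantic.ValidationError as exc:
            raise ScenarioValidationError(
                f"{drug_path}: intervention {r.intervention_id!r} item "
                f"{r.item_id!r}: {exc.errors()[0]['msg']}"
            ) from exc
        _channel(r.intervention_id, r.channel)["drug_lines"].append(line)
    for r in time_rows:
        try:
            line = ProviderTimeLine(
                cadre_id=r.cadre_id,
                minutes_per_visit=r.minutes_per_visit,
                n_visits=r.n_visits,
            )
        except pydantic.ValidationError as exc:
            raise ScenarioValidationError(
                f"{time_path}: intervention {r.intervention_id!r} cadre "
                f"{r.cadre_id!r}: {exc.errors()[0]['msg']}"
            ) from exc
        _channel(r.intervention_id, r.channel)["time_lines"].append(line)
    for r in visit_rows:
        slot = _channel(r.intervention_id, r.channel)
        if slot["visit_profile"] is not None:
            raise ScenarioValidationError(
                f"{visits_path}: duplicate visit row for intervention "
                f"{r.intervention_id!r} channel {r.channel!r}"
            )
        try:
            slot["visit_profile"] = VisitProfile(
                opv_per_case=r.opv_per_case, ipd_per_case=r.ipd_per_case
            )
        except pydantic.ValidationError as exc:
            raise ScenarioValidationError(
                f"{visits_path}: intervention {r.intervention_id!r}: "
                f"{exc.errors()[0]['msg']}"
            ) from exc

    profiles: Dict[str, InterventionProfile] = {}
    for iv, chans in channels.items():
        mix = channel_mix.get(iv)
        if mix is None:
            if len(chans) == 1:
                mix = {next(iter(chans)): 1.0}
            else:
                raise ScenarioValidationError(
                    f"intervention {iv!r} has {len(chans)} channels but no "
                    "channel_mix entry in scenario.json"
                )
        unknown = set(mix) - set(chans)
        if unknown:
            raise ScenarioValidationError(
                f"intervention {iv!r}: channel_mix names unknown channels "
                f"{sorted(unknown)}"
            )
        built = {}
        for ch_name, parts in chans.items():
            if ch_name not in mix:
                raise ScenarioValidationError(
                    f"intervention {iv!r}: channel {ch_name!r} missing from "
                    "channel_mix"
                )
            try:
                built[ch_name] = ChannelProfile(
                    drug_lines=tuple(parts["drug_lines"]),
                    time_lines=tuple(parts["time_lines"]),
                    visit_profile=parts["visit_profile"]
                    or VisitProfile(opv_per_case=0.0, ipd_per_case=0.0),
                    mix_fraction=mix[ch_name],
                )
            except pydantic.ValidationError as exc:
                raise ScenarioValidationError(
                    f"intervention {iv!r}: channel mix fraction for {ch_name!r}: "
                    f"{exc.errors()[0]['msg']}"
                ) from exc
        try:
            profiles[iv] = InterventionProfile(intervention_id=iv, channels=built)
        except pydantic.ValidationError as exc:
            raise ScenarioValidationError(
                f"intervention {iv!r}: {exc.errors()[0]['msg']}"
            ) from exc
    return profiles


def write_profiles(
    profiles: Mapping[str, InterventionProfile],
    drug_path: PathLike,
    time_path: PathLike,
    visits_path: PathLike,
) -> Dict[str, Dict[str, float]]:
    """Write the three flat treatment-input tables; returns the channel mix
    mapping for inclusion in scenario.json."""
    drug_rows, time_rows, visit_rows = [], [], []
    mix: Dict[str, Dict[str, float]] = {}
    for iv in sorted(profiles):
        profile = profiles[iv]
        mix[iv] = {}
        for ch_name in sorted(profile.channels):
            ch = profile.channels[ch_name]
            mix[iv][ch_name] = ch.mix_fraction
            for line in ch.drug_lines:
                drug_rows.append(
                    {"intervention_id": iv, "channel": ch_name, **line.model_dump()}
                )
            for line in ch.time_lines:
                time_rows.append(
                    {"intervention_id": iv, "channel": ch_name, **line.model_dump()}
                )
            visit_rows.append(
                {
                    "intervention_id": iv,
                    "channel": ch_name,
                    **ch.visit_profile.model_dump(),
                }
            )
    _to_csv(
        pd.DataFrame(
            drug_rows,
            columns=[
                "intervention_id",
                "channel",
                "item_id",
                "unit_price",
                "units_per_case",
                "pct_receiving",
            ],
        ),
        drug_path,
    )
    _to_csv(
        pd.DataFrame(
            time_rows,
            columns=[
                "intervention_id",
                "channel",
                "cadre_id",
                "minutes_per_visit",
                "n_visits",
            ],
        ),
        time_path,
    )
    _to_csv(pd.DataFrame(visit_rows), visits_path)
    return mix


# ---------------------------------------------------------------------------
# scenario bundle
# ---------------------------------------------------------------------------

_SCENARIO_FILES = (
    "populations",
    "needs",
    "drug_lines",
    "time_lines",
    "visits",
    "cadres",
    "hotel_costs",
    "shares",
)


def load_scenario(json_path: PathLike, percent: bool = False) -> Scenario:
    """Load and fully validate a scenario from its ``scenario.json``.

    Raises :class:`ScenarioValidationError` for a missing file, an
    out-of-range value, or a dangling cross-reference, naming the offending
    table and row.
    """
    json_path = Path(json_path)
    if not json_path.exists():
        raise ScenarioValidationError(f"missing scenario file: {json_path}")
    try:
        spec = json.loads(json_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ScenarioValidationError(f"{json_path}: invalid JSON ({exc})") from exc

    for key in ("name", "year_range", "files"):
        if key not in spec:
            raise ScenarioValidationError(f"{json_path}: missing key {key!r}")
    files = spec["files"]
    missing = [k for k in _SCENARIO_FILES if k not in files]
    if missing:
        raise ScenarioValidationError(
            f"{json_path}: missing file pointers for {missing}"
        )
    base = json_path.parent
    paths = {k: base / files[k] for k in _SCENARIO_FILES}

    yr = spec["year_range"]
    year_range = (int(yr["start"]), int(yr["end"]))

    profiles = read_profiles(
        paths["drug_lines"],
        paths["time_lines"],
        paths["visits"],
        spec.get("channel_mix", {}),
        percent=percent,
    )
    try:
        program_items = {
            cat: ProgramCostItem(**item)
            for cat, item in spec.get("program_costs", {}).items()
        }
        program_costs = ProgramCostSpec(items=program_items)
    except pydantic.ValidationError as exc:
        raise ScenarioValidationError(
            f"{json_path}: program_costs: {exc.errors()[0]['msg']}"
        ) from exc

    from .types import UnitCostDB  # local import to keep module top tidy

    try:
        scenario = Scenario(
            name=spec["name"],
            year_range=year_range,
            populations=tuple(read_populations(paths["populations"])),
            needs=tuple(read_needs(paths["needs"], percent=percent)),
            profiles=profiles,
            cost_db=UnitCostDB(
                cadres=read_cadres(paths["cadres"]),
                hotel=read_hotel_costs(paths["hotel_costs"]),
                shares=read_shares(paths["shares"], percent=percent),
            ),
            program_costs=program_costs,
        )
    except pydantic.ValidationError as exc:
        raise ScenarioValidationError(
            f"{json_path}: {exc.errors()[0]['msg']}"
        ) from exc
    return scenario


def write_scenario(
    scenario: Scenario, out_dir: PathLike, json_name: str = "scenario.json"
) -> Path:
    """Write a scenario as its full CSV + JSON file set; returns the JSON path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_populations(scenario.populations, out_dir / "populations.csv")
    write_needs(scenario.needs, out_dir / "needs.csv")
    mix = write_profiles(
        scenario.profiles,
        out_dir / "drug_lines.csv",
        out_dir / "time_lines.csv",
        out_dir / "visits.csv",
    )
    write_cadres(scenario.cost_db.cadres, out_dir / "cadres.csv")
    write_hotel_costs(scenario.cost_db.hotel, out_dir / "hotel_costs.csv")
    write_shares(scenario.cost_db.shares, out_dir / "shares.csv")
    spec = {
        "name": scenario.name,
        "year_range": {
            "start": scenario.year_range[0],
            "end": scenario.year_range[1],
        },
        "files": {
            "populations": "populations.csv",
            "needs": "needs.csv",
            "drug_lines": "drug_lines.csv",
            "time_lines": "time_lines.csv",
            "visits": "visits.csv",
            "cadres": "cadres.csv",
            "hotel_costs": "hotel_costs.csv",
            "shares": "shares.csv",
        },
        "channel_mix": mix,
        "program_costs": {
            cat: {
                k: v
                for k, v in item.model_dump().items()
                if v is not None
            }
            for cat, item in sorted(scenario.program_costs.items.items())
        },
    }
    json_path = out_dir / json_name
    json_path.write_text(
        json.dumps(spec, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return json_path


# ---------------------------------------------------------------------------
# results export
# ---------------------------------------------------------------------------


def write_results(results: pd.DataFrame, path: PathLike) -> None:
    """Write a tidy cost-results table (intervention_id, year, component, usd).

    Components are relabelled for export (other_direct -> other_recurrent,
    indirect -> capital); a comment header records the mapping. Values are
    written at full precision so a read-back is bit-exact.
    """
    if results.empty:
        raise ScenarioValidationError("results table is empty")
    expected = {"intervention_id", "year", "component", "usd"}
    if set(results.columns) != expected:
        raise ScenarioValidationError(
            f"results table must have columns {sorted(expected)}, "
            f"got {list(results.columns)}"
        )
    out = results.copy()
    out["component"] = out["component"].map(EXPORT_LABELS)
    if out["component"].isna().any():
        raise ScenarioValidationError("results table has unknown component names")
    # shortest round-trip repr so a read-back reproduces values bit-exactly
    out["usd"] = [repr(float(v)) for v in out["usd"]]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_RESULTS_HEADER_NOTE)
        out.to_csv(fh, index=False, lineterminator="\n")


def read_results(path: PathLike) -> pd.DataFrame:
    df = _read_csv(path)
    df["component"] = df["component"].map(_IMPORT_LABELS)
    if df["component"].isna().any():
        raise ScenarioValidationError(f"{path}: unknown component label")
    return df


# ---------------------------------------------------------------------------
# facility cost data and impacts
# ---------------------------------------------------------------------------


def read_facilities(path: PathLike) -> pd.DataFrame:
    """Read and validate a facility-level cost table for share estimation."""
    df = _read_csv(path)
    _rows_to_models(df, FacilityCostRecord, path)  # row-wise validation
    return df


def write_facilities(df: pd.DataFrame, path: PathLike) -> None:
    _to_csv(df, path)


def read_impacts(path: PathLike) -> pd.DataFrame:
    """Read a lives-saved table: scenario, [intervention_id,] year, lives_saved."""
    df = _read_csv(path)
    required = {"scenario", "year", "lives_saved"}
    if not required.issubset(df.columns):
        raise ScenarioValidationError(
            f"{path}: impacts table needs columns {sorted(required)}"
        )
    return df


# ---------------------------------------------------------------------------
# helper: linear interpolation of interior years
# ---------------------------------------------------------------------------


def fill_years_linear(
    df: pd.DataFrame,
    group_cols: Sequence[str],
    value_cols: Sequence[str],
    years: Iterable[int],
    year_col: str = "year",
) -> pd.DataFrame:
    """Fill missing interior years by linear interpolation within each group.

    Coverage and population tables require an explicit row per year; this
    optional helper expands a sparse table (e.g. endpoints only) to the full
    annual grid. Values outside the supplied span are not extrapolated — each
    group must include the first and last requested year.
    """
    years = sorted(years)
    out_frames = []
    for key, grp in df.groupby(list(group_cols)):
        grp = grp.sort_values(year_col)
        have = grp[year_col].tolist()
        if have[0] > years[0] or have[-1] < years[-1]:
            raise ScenarioValidationError(
                f"group {key!r}: supplied years {have} do not span "
                f"[{years[0]}, {years[-1]}]"
            )
        grid = (
            grp.set_index(year_col)
            .reindex(range(years[0], years[-1] + 1))
            .sort_index()
        )
        grid[list(value_cols)] = grid[list(value_cols)].interpolate(method="index")
        for i, col in enumerate(group_cols):
            grid[col] = key[i] if isinstance(key, tuple) else key
        grid = grid.reset_index().rename(columns={"index": year_col})
        out_frames.append(grid[grid[year_col].isin(years)])
    out = pd.concat(out_frames, ignore_index=True)
    return out[list(group_cols) + [year_col] + list(value_cols)]
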