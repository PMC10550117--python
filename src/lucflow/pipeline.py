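"""End-to-end orchestration: time-series fold-change runs and the
replicate-precision and bulk-agreement reports recomputed from the
supplementary-style CSV dialects.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, LucFlowError
from .fcs_io import DEFAULT_ROLE_MAP, EventTable, ReplicateRecord, read_replicate_csv
from .gating import GateConfig
from .quantify import (
    FoldChangeResult,
    PrecisionReport,
    TubeSummary,
    analyze_tube,
    compare_to_bulk,
    fold_change_scheme_A,
    fold_change_scheme_B,
    precision_report,
)

REFERENCE_CONSTRUCT = "Promoter"
REFERENCE_TIME = -48.0
BACKGROUND_CONSTRUCT = "PUER"


@dataclass
class RunConfig:
    """Resolved configuration for a pipeline run."""

    role_map: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_ROLE_MAP))
    gates: GateConfig = field(default_factory=GateConfig)
    scheme: str = "A"
    reference_construct: str = REFERENCE_CONSTRUCT
    reference_time: float = REFERENCE_TIME
    background_construct: str = BACKGROUND_CONSTRUCT
    min_count: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("A", "B"):
            raise ContractError("scheme must be 'A' or 'B'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        gates = GateConfig.from_dict(data.pop("gates", {}))
        return cls(gates=gates, **data)

    def to_yaml(self, path: str | Path) -> Path:
        data = {
            "role_map": self.role_map,
            "gates": self.gates.to_dict(),
            "scheme": self.scheme,
            "reference_construct": self.reference_construct,
            "reference_time": self.reference_time,
            "background_construct": self.background_construct,
            "min_count": self.min_count,
            "master_seed": self.master_seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
        return Path(path)


@dataclass
class TubeOutcome:
    """Per-tube result of a batch run; failures are first-class records."""

    tube_id: str
    construct: str
    time_hours: float
    summary: TubeSummary | None = None
    fold_change: FoldChangeResult | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


def run_timeseries(
    tubes: Sequence[tuple[EventTable, str, float]],
    config: RunConfig | None = None,
) -> list[TubeOutcome]:
    """Gate and summarize every tube, then compute per-tube fold change.

    ``tubes`` holds (table, construct, time_hours) triples and must include
    the reference tube (reference construct at the reference time). Under
    scheme B a background tube (``background_construct``) is also required,
    matched by timepoint when one exists at the tube's timepoint and
    falling back to the single background tube otherwise. Gate failures on
    individual tubes never abort the batch.
    """
    config = config or RunConfig()
    outcomes: list[TubeOutcome] = []
    for table, construct, time_hours in tubes:
        outcome = TubeOutcome(table.tube_id, construct, float(time_hours))
        try:
            outcome.summary = analyze_tube(
                table, config.gates, min_count=config.min_count
            )
        except LucFlowError as exc:
            outcome.error = f"{type(exc).__name__}: {exc}"
            _warnings.warn(
                f"tube {table.tube_id!r} failed gating: {outcome.error}",
                stacklevel=2,
            )
        outcomes.append(outcome)

    def find(construct: str, time_hours: float | None) -> TubeOutcome | None:
        hits = [
            o for o in outcomes
            if o.ok and o.construct == construct
            and (time_hours is None or o.time_hours == time_hours)
        ]
        return hits[0] if hits else None

    reference = find(config.reference_construct, config.reference_time)
    if config.scheme == "A":
        if reference is None:
            raise ContractError(
                f"reference tube ({config.reference_construct!r} at "
                f"{config.reference_time} h) missing or failed"
            )
        for o in outcomes:
            if not o.ok:
                continue
            try:
                o.fold_change = fold_change_scheme_A(
                    reference.summary.f_sample,
                    reference.summary.f_control,
                    o.summary.f_sample,
                    o.summary.f_control,
                    reference_tube_id=reference.tube_id,
                )
            except LucFlowError as exc:
                o.error = f"{type(exc).__name__}: {exc}"
    else:
        background_any = find(config.background_construct, None)
        if background_any is None:
            raise ContractError(
                f"scheme B needs a background tube "
                f"({config.background_construct!r}), none present or all failed"
            )
        for o in outcomes:
            if not o.ok or o.construct == config.background_construct:
                continue
            background = (
                find(config.background_construct, o.time_hours) or background_any
            )
            try:
                o.fold_change = fold_change_scheme_B(
                    o.summary.f_sample,
                    o.summary.f_control,
                    background.summary.f_sample,
                    background.summary.f_control,
                    reference_tube_id=background.tube_id,
                )
            except LucFlowError as exc:
                o.error = f"{type(exc).__name__}: {exc}"

    outcomes.sort(key=lambda o: (o.construct, o.time_hours))
    return outcomes


def reproduce_precision(s11_path: str | Path) -> PrecisionReport:
    """Replicate CVs of MFI, SI, and fold change from an S11-dialect CSV."""
    records = read_replicate_csv(s11_path, "s11")
    return precision_report(records)


def bulk_fold_changes(
    records: Sequence[ReplicateRecord],
    reference: tuple[str, float] = (REFERENCE_CONSTRUCT, REFERENCE_TIME),
    replicate_level: bool = False,
) -> dict[tuple[str, float], float]:
    """Per-(construct, time) bulk fold change from S12-dialect records.

    Luminescence alone is used (deposited values carry no separate protein
    normalization). Default is mean-level: mean luminescence per point
    divided by the mean luminescence of the reference point. With
    ``replicate_level`` the ratio is taken per replicate (paired by
    replicate number against the reference) and then averaged.
    """
    frame = pd.DataFrame(
        {
            "construct": r.construct,
            "replicate": r.replicate,
            "time": r.values["time_hours"],
            "lum": r.values["luminescence"],
        }
        for r in records
    )
    ref_rows = frame[(frame.construct == reference[0]) & (frame.time == reference[1])]
    if ref_rows.empty:
        raise ContractError(f"reference point {reference} absent from bulk table")
    if replicate_level:
        ref_by_rep = ref_rows.set_index("replicate")["lum"]
        frame = frame[frame.replicate.isin(ref_by_rep.index)]
        frame = frame.assign(fc=frame.lum / frame.replicate.map(ref_by_rep))
        grouped = frame.groupby(["construct", "time"])["fc"].mean()
    else:
        ref_mean = ref_rows.lum.mean()
        grouped = frame.groupby(["construct", "time"])["lum"].mean() / ref_mean
    return {(c, float(t)): float(v) for (c, t), v in grouped.items()}


def flow_fold_changes(
    records: Sequence[ReplicateRecord],
    reference: tuple[str, float] = (REFERENCE_CONSTRUCT, REFERENCE_TIME),
    replicate_level: bool = False,
) -> dict[tuple[str, float], float]:
    """Per-(construct, time) flow fold change from S13-dialect records.

    Applies the scheme-A formula to the deposited control and sample
    Luciferase medians: background-subtracted signal per row is
    ``sample_median - control_median``; the fold change is its (mean-level
    or per-replicate) ratio against the reference point.
    """
    frame = pd.DataFrame(
        {
            "construct": r.construct,
            "replicate": r.replicate,
            "time": r.values["time_hours"],
            "signal": r.values["sample_median"] - r.values["control_median"],
        }
        for r in records
    )
    ref_rows = frame[(frame.construct == reference[0]) & (frame.time == reference[1])]
    if ref_rows.empty:
        raise ContractError(f"reference point {reference} absent from flow table")
    if replicate_level:
        ref_by_rep = ref_rows.set_index("replicate")["signal"]
        frame = frame[frame.replicate.isin(ref_by_rep.index)]
        frame = frame.assign(fc=frame.signal / frame.replicate.map(ref_by_rep))
        grouped = frame.groupby(["construct", "time"])["fc"].mean()
    else:
        ref_mean = ref_rows.signal.mean()
        if ref_mean <= 0:
            raise ContractError("reference point has no signal above background")
        grouped = frame.groupby(["construct", "time"])["signal"].mean() / ref_mean
    return {(c, float(t)): float(v) for (c, t), v in grouped.items()}


def reproduce_bulk_comparison(
    s12_path: str | Path,
    s13_path: str | Path,
    replicate_level: bool = False,
) -> tuple[pd.DataFrame, float]:
    """Matched bulk vs flow fold changes and their squared correlation.

    Returns a table with one row per matched (construct, time) point —
    bulk and flow fold change plus their flow/bulk ratio — and the r^2
    across matched points. Unmatched construct labels are an error.
    """
    bulk_records = read_replicate_csv(s12_path, "s12")
    flow_records = read_replicate_csv(s13_path, "s13")
    bulk_constructs = {r.construct for r in bulk_records}
    flow_constructs = {r.construct for r in flow_records}
    if bulk_constructs != flow_constructs:
        raise ContractError(
            "construct labels differ between bulk and flow tables: "
            f"bulk-only={sorted(bulk_constructs - flow_constructs)}, "
            f"flow-only={sorted(flow_constructs - bulk_constructs)}"
        )
    bulk = bulk_fold_changes(bulk_records, replicate_level=replicate_level)
    flow = flow_fold_changes(flow_records, replicate_level=replicate_level)
    keys = sorted(set(bulk) & set(flow))
    table = pd.DataFrame(
        {
            "construct": [k[0] for k in keys],
            "time_hours": [k[1] for k in keys],
            "bulk_fold_change": [bulk[k] for k in keys],
            "flow_fold_change": [flow[k] for k in keys],
        }
    )
    table["flow_over_bulk"] = table.flow_fold_change / table.bulk_fold_change
    r_squared = compare_to_bulk(bulk, flow)
    return table, r_squared


def outcomes_to_frame(outcomes: Sequence[TubeOutcome]) -> pd.DataFrame:
    """Flatten batch outcomes into a tidy table (one row per tube)."""
    rows = []
    for o in outcomes:
        row: dict[str, object] = {
            "tube_id": o.tube_id,
            "construct": o.construct,
            "time_hours": o.time_hours,
            "status": "ok" if o.ok else "failed",
            "error": o.error or "",
        }
        if o.summary is not None:
            row.update(
                f_sample=o.summary.f_sample,
                f_control=o.summary.f_control,
                p84_sample=o.summary.p84_sample,
                n_sample=o.summary.n_sample,
                n_control=o.summary.n_control,
            )
        if o.fold_change is not None:
            row.update(
                fold_change=o.fold_change.L_sample,
                scheme=o.fold_change.scheme,
                reference_tube=o.fold_change.reference_tube_id,
            )
        rows.append(row)
    return pd.DataFrame(rows)
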