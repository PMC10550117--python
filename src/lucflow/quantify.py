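"""Summary statistics for gated tubes: median fluorescence, separation
index, spike-in fold change (two schemes), replicate CV, and agreement
with bulk assays.

All statistics operate on raw linear channel values. Two fold-change
schemes are provided, differing in which cell line is spiked into the
tube as internal control:

* **Scheme A** — every tube is spiked with Luciferase-negative cells, so
  background is subtracted within the tube and the reference signal comes
  from a separate (undifferentiated reference) tube::

      L = (f_sample2 - f_control2) / (f_sample1 - f_control1)

  Exactly invariant to an additive per-tube shift.

* **Scheme B** — every tube is spiked with reference-expressing cells;
  background is estimated from a separate Luc- tube and scaled into this
  tube through the shared spike::

      b_sample = f_puer * f_sample_s / f_puer_s
      L = (f_sample - b_sample) / (f_sample_s - b_sample)

  Exactly invariant to a multiplicative per-tube factor.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ContractError,
    DegenerateSpikeError,
    DegenerateSpreadError,
    ReferenceBackgroundError,
    UndefinedCorrelationError,
)
from .fcs_io import EventTable, ReplicateRecord
from .gating import GateConfig, GatingResult, apply_gates

SI_CONSTANT = 0.995  # calibrates (p84 - median) to one robust SD under normality


@dataclass
class TubeSummary:
    """Median Luciferase fluorescence of the two subpopulations of a tube."""

    tube_id: str
    f_sample: float
    f_control: float
    p84_sample: float
    p84_control: float
    n_sample: int
    n_control: int
    thresholds_used: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class FoldChangeResult:
    """Fold change relative to the undifferentiated reference."""

    L_sample: float
    scheme: str  # "A_puer_spike" | "B_promoter_spike"
    b_sample: float | None = None
    reference_tube_id: str | None = None
    negative_signal: bool = False  # background-subtracted signal < 0, flagged


@dataclass
class PrecisionReport:
    """Per-construct replicate precision for each statistic."""

    # statistic -> construct -> {"mean": .., "sd": .., "cv": .., "n": ..}
    per_construct: dict[str, dict[str, dict[str, float]]]
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def cv_range(self, statistic: str) -> tuple[float, float]:
        """(min, max) CV across constructs for ``statistic``."""
        cvs = [g["cv"] for g in self.per_construct.get(statistic, {}).values()]
        if not cvs:
            raise ContractError(f"no CVs available for statistic {statistic!r}")
        return min(cvs), max(cvs)


def median_fluorescence(values: Iterable[float]) -> float:
    """Statistical median; even counts average the two central order stats."""
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if vals.size == 0:
        raise ContractError("median of an empty set is undefined")
    if not np.all(np.isfinite(vals)):
        raise ContractError("median requires finite values")
    return float(np.median(vals))


def percentile_84(values: Iterable[float]) -> float:
    """84th percentile, linear interpolation between closest order statistics.

    The interpolation rule is numpy's ``linear`` method: with sorted values
    x_0..x_{n-1}, the percentile sits at fractional rank 0.84*(n-1).
    """
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if vals.size < 2:
        raise ContractError("84th percentile needs at least 2 values")
    if not np.all(np.isfinite(vals)):
        raise ContractError("percentile requires finite values")
    return float(np.percentile(vals, 84, method="linear"))


def separation_index(mu_sample: float, mu_puer: float, p84_puer: float) -> float:
    """SI = 0.995 * (mu_sample - mu_puer) / (p84_puer - mu_puer).

    The denominator is a robust SD of the negative population (its 84th
    percentile minus its median); the sign follows the numerator.
    """
    spread = p84_puer - mu_puer
    if spread <= 0:
        raise DegenerateSpreadError(
            f"negative-population spread is {spread}; p84 must exceed the median"
        )
    return SI_CONSTANT * (mu_sample - mu_puer) / spread


def fold_change_scheme_A(
    f_sample1: float,
    f_control1: float,
    f_sample2: float,
    f_control2: float,
    reference_tube_id: str | None = None,
) -> FoldChangeResult:
    """Fold change with a Luc- spike in both tubes (within-tube background).

    Tube 1 is the undifferentiated reference, tube 2 the sample. Negative
    background-subtracted sample signal is flagged, never clipped.
    """
    ref_signal = f_sample1 - f_control1
    if ref_signal <= 0:
        raise ReferenceBackgroundError(
            "reference tube has no signal above its spiked background "
            f"(f_sample1={f_sample1}, f_control1={f_control1})"
        )
    signal = f_sample2 - f_control2
    negative = signal < 0
    if negative:
        _warnings.warn(
            "background-subtracted sample signal is negative; "
            "result flagged, not clipped",
            stacklevel=2,
        )
    return FoldChangeResult(
        L_sample=signal / ref_signal,
        scheme="A_puer_spike",
        reference_tube_id=reference_tube_id,
        negative_signal=bool(negative),
    )


def fold_change_scheme_B(
    f_sample: float,
    f_sample_s: float,
    f_puer: float,
    f_puer_s: float,
    reference_tube_id: str | None = None,
) -> FoldChangeResult:
    """Fold change with a reference-expressing spike (within-tube reference).

    ``f_sample``/``f_sample_s`` are sample and spike medians in the sample
    tube; ``f_puer``/``f_puer_s`` are the Luc- cells and their spike in the
    background tube. Background is ``b = f_puer * f_sample_s / f_puer_s``.
    """
    if f_puer_s <= 0:
        raise ContractError("spike median in the background tube must be positive")
    b_sample = f_puer * f_sample_s / f_puer_s
    if f_sample_s <= b_sample:
        raise DegenerateSpikeError(
            f"spike median {f_sample_s} does not exceed estimated background "
            f"{b_sample}"
        )
    signal = f_sample - b_sample
    negative = signal < 0
    if negative:
        _warnings.warn(
            "background-subtracted sample signal is negative; "
            "result flagged, not clipped",
            stacklevel=2,
        )
    return FoldChangeResult(
        L_sample=signal / (f_sample_s - b_sample),
        scheme="B_promoter_spike",
        b_sample=b_sample,
        reference_tube_id=reference_tube_id,
        negative_signal=bool(negative),
    )


def coefficient_of_variation(values: Iterable[float]) -> float:
    """CV in percent: 100 * sample SD (n-1 denominator) / mean."""
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if vals.size < 2:
        raise ContractError("CV needs at least 2 values")
    mean = vals.mean()
    if mean == 0:
        raise ContractError("CV undefined for zero mean")
    return float(100.0 * vals.std(ddof=1) / mean)


def analyze_tube(
    table: EventTable,
    config: GateConfig | None = None,
    min_count: int = 100,
    gating: GatingResult | None = None,
) -> TubeSummary:
    """Gate a tube and summarize its Luciferase channel.

    Applies the full gate chain (unless a precomputed ``gating`` is given),
    then computes median and 84th-percentile Luciferase fluorescence of the
    CFSE- sample and CFSE+ control subpopulations. Subpopulations smaller
    than ``min_count`` attach a low-count warning to the summary.
    """
    config = config or GateConfig()
    result = gating if gating is not None else apply_gates(table, config)
    luc = table.channel("luciferase")
    sample = luc[result.mask("sample")]
    control = luc[result.mask("control_spike")]

    warnings = list(result.warnings)
    for name, sub in (("sample", sample), ("control", control)):
        if sub.size < min_count:
            msg = (f"tube {table.tube_id!r}: {name} subpopulation has "
                   f"{sub.size} events (< {min_count})")
            warnings.append(msg)
            _warnings.warn(msg, stacklevel=2)

    return TubeSummary(
        tube_id=table.tube_id,
        f_sample=median_fluorescence(sample),
        f_control=median_fluorescence(control),
        p84_sample=percentile_84(sample) if sample.size >= 2 else float(sample[0]),
        p84_control=percentile_84(control) if control.size >= 2 else float(control[0]),
        n_sample=int(sample.size),
        n_control=int(control.size),
        thresholds_used=dict(result.thresholds_used),
        warnings=warnings,
    )


def precision_report(
    records: Sequence[ReplicateRecord],
    statistics: Sequence[str] = ("mfi", "si", "fold_change"),
) -> PrecisionReport:
    """Replicate CV per construct per statistic, with across-construct ranges.

    Groups with fewer than 2 replicates are skipped with a warning rather
    than failing the whole report.
    """
    per_construct: dict[str, dict[str, dict[str, float]]] = {s: {} for s in statistics}
    skipped: list[tuple[str, str]] = []
    constructs = sorted({r.construct for r in records})
    for stat in statistics:
        for construct in constructs:
            vals = [
                r.values[stat]
                for r in records
                if r.construct == construct and stat in r.values
            ]
            if len(vals) < 2:
                skipped.append((construct, stat))
                _warnings.warn(
                    f"construct {construct!r}: fewer than 2 replicates for "
                    f"{stat!r}; group skipped",
                    stacklevel=2,
                )
                continue
            arr = np.asarray(vals, dtype=float)
            per_construct[stat][construct] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "cv": coefficient_of_variation(arr),
                "n": float(arr.size),
            }
    return PrecisionReport(per_construct=per_construct, skipped=skipped)


def compare_to_bulk(
    bulk: Mapping[tuple, float], flow: Mapping[tuple, float]
) -> float:
    """Squared Pearson correlation between matched bulk and flow fold changes.

    ``bulk`` and ``flow`` map (construct, time) keys to per-point mean fold
    changes; only keys present in both are used. Requires >= 3 matched
    points and nonzero variance in both vectors.
    """
    keys = sorted(set(bulk) & set(flow))
    if len(keys) < 3:
        raise ContractError(
            f"need >= 3 matched (construct, time) points, got {len(keys)}"
        )
    x = np.asarray([bulk[k] for k in keys], dtype=float)
    y = np.asarray([flow[k] for k in keys], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: one method's fold changes are constant"
        )
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)
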