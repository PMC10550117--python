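"""Four-stage gating: debris exclusion, singlet selection, dead-cell
exclusion, and CFSE spike-in deconvolution.

Stage order is fixed (debris -> singlets -> live -> spike split) and each
stage only removes events. Every gate runs in ``manual`` mode (threshold
from config) or ``auto`` mode (density-valley threshold found on the data);
realized thresholds are always recorded so a run can be reproduced.

Automatic thresholds come from a kernel-density estimate on natural-log
values: the threshold is the minimum of the density between the two
highest modes. Fluorescence is approximately log-normal per
subpopulation, which makes the log-scale valley well defined whenever two
populations are actually separated. Nonpositive values are clamped to the
smallest positive observation for density estimation only; raw values are
never modified.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from scipy.stats import gaussian_kde

from .errors import (
    ContractError,
    DegenerateSplitError,
    InsufficientDataError,
    NoValleyError,
)
from .fcs_io import EventTable

GATE_ORDER = ("debris", "singlets", "live", "spike")
LABELS = ("debris", "doublet", "dead", "control_spike", "sample", "unassigned")

_MIN_AUTO_EVENTS = 100
_KDE_GRID = 512
_KDE_MAX_POINTS = 20_000  # deterministic subsample cap for KDE cost
_VALLEY_DEPTH_RATIO = 0.8  # valley must dip below this fraction of both modes
_MIN_SIDE_FRACTION = 0.01  # each side of a valley must hold >=1% of the events


class GateWarning(UserWarning):
    """Raised (as a warning) when an auto gate falls back to a default."""


@dataclass
class GateConfig:
    """Per-gate mode and thresholds plus auto-gate parameters.

    ``*_mode`` is ``"auto"`` or ``"manual"``. Manual thresholds must be
    positive when the corresponding mode is ``"manual"``; in auto mode the
    debris floors serve as the fallback when no density valley exists.
    """

    debris_mode: str = "auto"
    fsc_min: float | None = None
    ssc_min: float | None = None

    singlet_mode: str = "auto"
    singlet_ratio_max: float | None = None
    singlet_k: float = 3.0  # r_max = median ratio + k * robust SD of ratios

    live_mode: str = "auto"
    viability_max: float | None = None

    spike_mode: str = "auto"
    cfse_threshold: float | None = None

    kde_bandwidth: str | float = "scott"
    min_mode_separation: float = 0.5  # natural-log units between the two modes

    def __post_init__(self) -> None:
        for gate, mode, thresholds in (
            ("debris", self.debris_mode, (self.fsc_min, self.ssc_min)),
            ("singlets", self.singlet_mode, (self.singlet_ratio_max,)),
            ("live", self.live_mode, (self.viability_max,)),
            ("spike", self.spike_mode, (self.cfse_threshold,)),
        ):
            if mode not in ("auto", "manual"):
                raise ContractError(f"{gate} gate mode must be auto or manual")
            if mode == "manual":
                for t in thresholds:
                    if t is None or t <= 0:
                        raise ContractError(
                            f"{gate} gate in manual mode needs positive threshold(s)"
                        )
        if self.singlet_ratio_max is not None and self.singlet_ratio_max <= 1:
            raise ContractError("singlet_ratio_max must exceed 1")

    @classmethod
    def from_dict(cls, data: dict) -> "GateConfig":
        return cls(**{k: v for k, v in data.items() if v is not None})

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GatingResult:
    """Per-event labels, realized thresholds, and label counts."""

    labels: np.ndarray  # array of str, one per event
    thresholds_used: dict[str, float]
    warnings: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in LABELS}

    def mask(self, *labels: str) -> np.ndarray:
        return np.isin(self.labels, labels)


def auto_threshold(
    values: Iterable[float],
    bandwidth: str | float = "scott",
    min_mode_separation: float = 0.5,
) -> float:
    """Density-valley threshold between the two highest modes of ``values``.

    A Gaussian KDE is fit to the natural logs of the (positive-clamped)
    values; local maxima of the density are the modes. The threshold is
    the exponentiated location of the minimum density between the two
    modes of highest density that are at least ``min_mode_separation``
    log-units apart (ties broken toward the lower valley). Deterministic
    for fixed input and bandwidth rule.
    """
    vals = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                      dtype=float)
    if vals.size < _MIN_AUTO_EVENTS:
        raise InsufficientDataError(
            f"auto threshold needs >= {_MIN_AUTO_EVENTS} values, got {vals.size}"
        )
    positive = vals[vals > 0]
    if positive.size == 0 or np.ptp(positive) == 0:
        raise InsufficientDataError("values have no positive spread")
    # clamp nonpositives to the smallest positive observation (KDE input only)
    logs = np.log(np.where(vals > 0, vals, positive.min()))
    if vals.size > _KDE_MAX_POINTS:
        step = vals.size // _KDE_MAX_POINTS + 1
        logs = logs[::step]
    if np.std(logs) == 0:
        raise InsufficientDataError("values have zero spread on the log scale")

    kde = gaussian_kde(logs, bw_method=bandwidth)
    grid = np.linspace(logs.min(), logs.max(), _KDE_GRID)
    dens = kde(grid)

    interior = np.arange(1, _KDE_GRID - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    modes = interior[is_max]
    if modes.size < 2:
        raise NoValleyError("density is unimodal; no valley to threshold at")

    # candidate = highest remaining mode that is far enough from the top mode
    # AND whose intervening valley dips well below both modes; KDE wiggles in
    # a tail produce shallow "valleys" that the depth criterion rejects
    order = modes[np.argsort(dens[modes])[::-1]]
    top = int(order[0])
    for cand in order[1:]:
        cand = int(cand)
        if abs(grid[cand] - grid[top]) < min_mode_separation:
            continue
        lo, hi = sorted((top, cand))
        between = dens[lo : hi + 1]
        valley = lo + int(np.argmin(between))  # argmin takes the lower tie
        if dens[valley] >= _VALLEY_DEPTH_RATIO * min(dens[top], dens[cand]):
            continue
        # reject valleys carved out by a handful of outliers
        below = float(np.mean(logs < grid[valley]))
        if min(below, 1.0 - below) < _MIN_SIDE_FRACTION:
            continue
        return float(np.exp(grid[valley]))
    raise NoValleyError(
        "no second mode with a sufficiently deep valley; treating as unimodal"
    )


def _auto_or(values: np.ndarray, config: GateConfig, fallback: float | None,
             gate: str, warnings: list[str]) -> float:
    try:
        return auto_threshold(values, config.kde_bandwidth, config.min_mode_separation)
    except (NoValleyError, InsufficientDataError) as exc:
        if fallback is None:
            fallback = 0.0
        msg = f"{gate} gate: auto threshold failed ({exc}); using floor {fallback}"
        warnings.append(msg)
        _warnings.warn(msg, GateWarning, stacklevel=3)
        return float(fallback)


def gate_debris(
    table: EventTable, config: GateConfig, _log: dict | None = None
) -> np.ndarray:
    """Keep-mask excluding debris: events low in both FSC-A and SSC-A.

    Keeps events with FSC-A >= fsc_min AND SSC-A >= ssc_min; in auto mode
    each floor is the density valley of its channel, falling back to the
    configured floor (with a warning) if the density is unimodal.
    """
    table.require_roles("fsc_a", "ssc_a")
    fsc, ssc = table.channel("fsc_a"), table.channel("ssc_a")
    warnings: list[str] = []
    if config.debris_mode == "manual":
        fsc_min, ssc_min = float(config.fsc_min), float(config.ssc_min)
    else:
        fsc_min = _auto_or(fsc, config, config.fsc_min, "debris/FSC-A", warnings)
        ssc_min = _auto_or(ssc, config, config.ssc_min, "debris/SSC-A", warnings)
    if _log is not None:
        _log.update({"fsc_min": fsc_min, "ssc_min": ssc_min})
        _log.setdefault("warnings", []).extend(warnings)
    return (fsc >= fsc_min) & (ssc >= ssc_min)


def gate_singlets(
    table: EventTable, config: GateConfig, _log: dict | None = None
) -> np.ndarray:
    """Keep-mask excluding cell clusters: high FSC-A relative to FSC-H.

    The cut is on the ratio FSC-A / FSC-H. In auto mode the ceiling is
    ``median(ratio) + k * 1.4826 * MAD(ratio)`` — a robust fit of the
    singlet diagonal plus ``k`` robust SDs (``k`` = ``singlet_k``).
    """
    table.require_roles("fsc_a", "fsc_h")
    fsc_a, fsc_h = table.channel("fsc_a"), table.channel("fsc_h")
    if not np.any(fsc_h > 0):
        raise ContractError("all FSC-H values are zero; singlet ratio undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fsc_h > 0, fsc_a / np.where(fsc_h > 0, fsc_h, 1.0), np.inf)
    if config.singlet_mode == "manual":
        r_max = float(config.singlet_ratio_max)
    else:
        finite = ratio[np.isfinite(ratio)]
        med = float(np.median(finite))
        mad = float(np.median(np.abs(finite - med)))
        r_max = med + config.singlet_k * 1.4826 * mad
    if _log is not None:
        _log["singlet_ratio_max"] = r_max
    return ratio <= r_max


def gate_live(
    table: EventTable, config: GateConfig, _log: dict | None = None
) -> np.ndarray:
    """Keep-mask excluding dead cells: high viability-dye fluorescence.

    Auto mode thresholds at the log-density valley between the live and
    dead dye populations; a unimodal density retains all events and logs
    a warning (threshold recorded as +inf).
    """
    table.require_roles("viability")
    dye = table.channel("viability")
    warnings: list[str] = []
    if config.live_mode == "manual":
        viability_max = float(config.viability_max)
    else:
        try:
            viability_max = auto_threshold(
                dye, config.kde_bandwidth, config.min_mode_separation
            )
        except (NoValleyError, InsufficientDataError) as exc:
            viability_max = np.inf
            msg = f"live gate: auto threshold failed ({exc}); retaining all events"
            warnings.append(msg)
            _warnings.warn(msg, GateWarning, stacklevel=2)
    if _log is not None:
        _log["viability_max"] = viability_max
        _log.setdefault("warnings", []).extend(warnings)
    return dye <= viability_max


def split_spike(
    table: EventTable, config: GateConfig, _log: dict | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Split live singlets into (CFSE+ control, CFSE- sample) masks.

    The two masks are disjoint and cover the input. An empty side is an
    error: the tube cannot be normalized without both subpopulations.
    """
    table.require_roles("cfse")
    cfse = table.channel("cfse")
    if config.spike_mode == "manual":
        threshold = float(config.cfse_threshold)
    else:
        try:
            threshold = auto_threshold(
                cfse, config.kde_bandwidth, config.min_mode_separation
            )
        except (NoValleyError, InsufficientDataError) as exc:
            raise DegenerateSplitError(
                f"no CFSE+/CFSE- separation found: {exc}"
            ) from exc
    control = cfse > threshold
    sample = ~control
    if _log is not None:
        _log["cfse_threshold"] = threshold
    if not control.any():
        raise DegenerateSplitError("no CFSE+ (spiked control) events above threshold")
    if not sample.any():
        raise DegenerateSplitError("no CFSE- (sample) events below threshold")
    return control, sample


def apply_gates(table: EventTable, config: GateConfig) -> GatingResult:
    """Run the full fixed-order chain and label every event.

    Labels partition the events: ``debris``, ``doublet``, ``dead``,
    ``control_spike``, ``sample`` (``unassigned`` never survives the
    chain but is part of the label vocabulary).
    """
    table.require_roles("fsc_a", "fsc_h", "ssc_a", "viability", "cfse", "luciferase")
    n = table.n_events
    labels = np.full(n, "unassigned", dtype=object)
    log: dict = {"warnings": []}
    idx = np.arange(n)

    keep = gate_debris(table, config, log)
    labels[~keep] = "debris"
    idx = idx[keep]

    sub = table.subset(labels == "unassigned")
    keep = gate_singlets(sub, config, log)
    labels[idx[~keep]] = "doublet"
    idx = idx[keep]

    sub = table.subset(labels == "unassigned")
    keep = gate_live(sub, config, log)
    labels[idx[~keep]] = "dead"
    idx = idx[keep]

    sub = table.subset(labels == "unassigned")
    control, sample = split_spike(sub, config, log)
    labels[idx[control]] = "control_spike"
    labels[idx[sample]] = "sample"

    warnings = log.pop("warnings")
    return GatingResult(
        labels=labels.astype(str), thresholds_used=log, warnings=warnings
    )
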