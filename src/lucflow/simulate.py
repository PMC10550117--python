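"""Synthetic single-tube flow-cytometry data and matched bulk-luminescence
measurements, with ground truth for every pipeline stage.

Generative model (all fluorescence log-normal per subpopulation):

* events are assigned to {debris, doublet, dead, spike, live sample} by a
  single multinomial draw over the spec fractions;
* live sample cells have Luciferase log-median ``log(expression_level)``;
* dead cells have Luciferase at ``autofluorescence_level`` *independently
  of* ``expression_level`` (dead cells autofluoresce but carry no
  functional reporter protein) and viability-dye levels ~30-fold above
  live cells;
* spike cells are CFSE-bright (~100-fold above unlabeled cells) with
  Luciferase at ``spike_expression_level`` (set this to the background
  level for a Luc- spike, or to the reference expression level for a
  reference-line spike);
* doublets double FSC-A (and fluorescence) at a matched FSC-H;
* debris sits ~10-fold low on both scatter channels;
* the per-tube effect ``x -> scale * x + shift`` is applied last to all
  fluorescence channels; scatter channels are unaffected.

RNG contract: numpy's PCG64 via ``default_rng``. ``simulate_experiment``
derives one child ``SeedSequence`` per tube by spawning from the master
seed, so the whole experiment is reproducible from a single integer and
tubes are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import ContractError
from .fcs_io import EventTable

CHANNELS = ["FSC-A", "FSC-H", "SSC-A", "BV421-A", "FITC-A", "AF647-A"]
CHANNEL_ROLES = {
    "fsc_a": "FSC-A",
    "fsc_h": "FSC-H",
    "ssc_a": "SSC-A",
    "viability": "BV421-A",
    "cfse": "FITC-A",
    "luciferase": "AF647-A",
}
_FLUOR = ["BV421-A", "FITC-A", "AF647-A"]

DEFAULT_LOG_SD = {
    "fsc": 0.25,
    "ssc": 0.30,
    "viability": 0.40,
    "cfse": 0.40,
    "luciferase": 0.50,
}

# fixed scale anchors (linear units)
_CELL_FSC_H = 50_000.0
_CELL_SSC = 30_000.0
_DEBRIS_SCATTER_FACTOR = 0.1
_LIVE_DYE = 100.0
_DEAD_DYE_FACTOR = 30.0
_CFSE_NEG = 100.0
_CFSE_POS_FACTOR = 100.0
_SINGLET_RATIO = 1.0
_SINGLET_RATIO_SD = 0.03


@dataclass
class SyntheticTubeSpec:
    """Generative parameters for one tube; serves as ground truth."""

    n_events: int = 10_000
    fractions: dict[str, float] = field(
        default_factory=lambda: {"debris": 0.05, "doublet": 0.05,
                                 "dead": 0.10, "spike": 0.20}
    )
    expression_level: float = 5_000.0
    spike_expression_level: float = 100.0
    autofluorescence_level: float = 100.0
    log_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOG_SD))
    tube_shift: float = 0.0  # additive, fluorescence channels only
    tube_scale: float = 1.0  # multiplicative, fluorescence channels only
    seed: int | np.random.SeedSequence = 0
    tube_id: str = "tube"

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ContractError("n_events must be positive")
        for name, frac in self.fractions.items():
            if name not in ("debris", "doublet", "dead", "spike"):
                raise ContractError(f"unknown population {name!r}")
            if not 0 <= frac <= 1:
                raise ContractError(f"fraction {name!r} must lie in [0, 1]")
        if sum(self.fractions.values()) > 1:
            raise ContractError("population fractions exceed 1")
        for name in ("expression_level", "spike_expression_level",
                     "autofluorescence_level"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if self.tube_scale <= 0:
            raise ContractError("tube_scale must be positive")

    @property
    def live_fraction(self) -> float:
        return 1.0 - sum(self.fractions.values())


@dataclass
class GroundTruth:
    """Realized per-tube truth for recovery tests."""

    counts: dict[str, int]
    viability: float  # live (sample+spike) over all intact cells
    rho: dict[str, float] = field(default_factory=dict)  # tube_id -> true L
    specs: dict[str, SyntheticTubeSpec] = field(default_factory=dict)


def _lognormal(rng: np.random.Generator, median: float, sd: float, n: int
               ) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sd, size=n))


def simulate_tube(spec: SyntheticTubeSpec) -> tuple[EventTable, GroundTruth]:
    """Draw one tube; fully deterministic given ``spec.seed``."""
    seed = (spec.seed if isinstance(spec.seed, np.random.SeedSequence)
            else np.random.SeedSequence(spec.seed))
    rng = np.random.default_rng(seed)
    names = ["debris", "doublet", "dead", "spike", "live"]
    probs = [spec.fractions["debris"], spec.fractions["doublet"],
             spec.fractions["dead"], spec.fractions["spike"],
             spec.live_fraction]
    membership = rng.choice(len(names), size=spec.n_events, p=probs)
    counts = {name: int(np.sum(membership == i)) for i, name in enumerate(names)}

    n = spec.n_events
    events = np.zeros((n, len(CHANNELS)), dtype=float)
    sd = spec.log_sd
    is_debris = membership == 0
    is_doublet = membership == 1
    is_dead = membership == 2
    is_spike = membership == 3
    is_live = membership == 4
    is_cell = ~is_debris

    # scatter: FSC-H anchors cell size; FSC-A follows the singlet diagonal,
    # doubled for doublets; debris is small on both axes
    fsc_h = _lognormal(rng, _CELL_FSC_H, sd["fsc"], n)
    fsc_h[is_debris] = _lognormal(
        rng, _CELL_FSC_H * _DEBRIS_SCATTER_FACTOR, sd["fsc"] * 1.5, counts["debris"]
    )
    ratio = _SINGLET_RATIO * np.exp(rng.normal(0, _SINGLET_RATIO_SD, n))
    ratio[is_doublet] *= 2.0
    fsc_a = fsc_h * ratio
    ssc = _lognormal(rng, _CELL_SSC, sd["ssc"], n)
    ssc[is_debris] = _lognormal(
        rng, _CELL_SSC * _DEBRIS_SCATTER_FACTOR, sd["ssc"] * 1.5, counts["debris"]
    )

    dye = _lognormal(rng, _LIVE_DYE, sd["viability"], n)
    dye[is_dead] = _lognormal(
        rng, _LIVE_DYE * _DEAD_DYE_FACTOR, sd["viability"], counts["dead"]
    )

    cfse = _lognormal(rng, _CFSE_NEG, sd["cfse"], n)
    cfse[is_spike] = _lognormal(
        rng, _CFSE_NEG * _CFSE_POS_FACTOR, sd["cfse"], counts["spike"]
    )

    # Luciferase: expression only in live sample cells and the spike; dead
    # cells sit at autofluorescence regardless of expression_level, drawn
    # from a stream independent of the expression-bearing draws so that the
    # dead-cell distribution is identical across expression levels at a
    # fixed seed.
    dead_rng = np.random.default_rng(seed.spawn(1)[0])
    luc = _lognormal(rng, spec.autofluorescence_level, sd["luciferase"], n)
    luc[is_live] = _lognormal(
        rng, spec.expression_level, sd["luciferase"], counts["live"]
    )
    luc[is_doublet] = 2 * _lognormal(
        rng, spec.expression_level, sd["luciferase"], counts["doublet"]
    )
    luc[is_dead] = _lognormal(
        dead_rng, spec.autofluorescence_level, sd["luciferase"], counts["dead"]
    )
    luc[is_spike] = _lognormal(
        rng, spec.spike_expression_level, sd["luciferase"], counts["spike"]
    )

    events[:, 0], events[:, 1], events[:, 2] = fsc_a, fsc_h, ssc
    events[:, 3], events[:, 4], events[:, 5] = dye, cfse, luc
    for ch in _FLUOR:
        j = CHANNELS.index(ch)
        events[:, j] = spec.tube_scale * events[:, j] + spec.tube_shift
    if np.any(events < 0):
        raise ContractError("tube effect produced negative intensities")

    intact = counts["dead"] + counts["spike"] + counts["live"]
    truth = GroundTruth(
        counts=counts,
        viability=(counts["spike"] + counts["live"]) / intact if intact else 1.0,
        specs={spec.tube_id: spec},
    )
    table = EventTable(
        tube_id=spec.tube_id,
        channel_names=list(CHANNELS),
        channel_roles=dict(CHANNEL_ROLES),
        events=events,
    )
    return table, truth


def simulate_experiment(
    specs: Sequence[SyntheticTubeSpec],
    reference_tube_id: str,
    master_seed: int = 0,
) -> tuple[list[EventTable], GroundTruth]:
    """Generate a multi-tube experiment with per-tube substreams.

    Exactly one spec must carry ``reference_tube_id``. Ground-truth fold
    change ``rho`` per tube is the ratio of its ``expression_level`` to the
    reference tube's.
    """
    ids = [s.tube_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ContractError("tube ids must be unique")
    matches = [s for s in specs if s.tube_id == reference_tube_id]
    if len(matches) != 1:
        raise ContractError(
            f"exactly one reference tube required; {len(matches)} spec(s) "
            f"match {reference_tube_id!r}"
        )
    reference = matches[0]

    children = np.random.SeedSequence(master_seed).spawn(len(specs))
    tables: list[EventTable] = []
    truth = GroundTruth(counts={}, viability=float("nan"))
    for spec, child in zip(specs, children):
        table, tube_truth = simulate_tube(replace(spec, seed=child))
        tables.append(table)
        truth.specs[spec.tube_id] = spec
        truth.rho[spec.tube_id] = spec.expression_level / reference.expression_level
        for pop, cnt in tube_truth.counts.items():
            truth.counts[f"{spec.tube_id}:{pop}"] = cnt
    return tables, truth


def simulate_bulk(
    expression_level: float,
    viability: float,
    n_cells: int,
    noise_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Bulk luminescence of a lysate: only live cells contribute signal.

    Returns ``expression_level * viability * n_cells * (1 + eps)`` with
    multiplicative log-normal noise of coefficient of variation
    ``noise_cv``. The matching protein-normalized readout divides by total
    cells (dead cells still contribute protein), so normalized bulk signal
    scales with viability — divide the return value by ``n_cells``.
    """
    if expression_level <= 0 or n_cells <= 0:
        raise ContractError("expression_level and n_cells must be positive")
    if not 0 < viability <= 1:
        raise ContractError("viability must lie in (0, 1]")
    if noise_cv < 0:
        raise ContractError("noise_cv must be nonnegative")
    signal = expression_level * viability * n_cells
    if noise_cv == 0:
        return float(signal)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    # mean-one log-normal noise
    eps = np.exp(rng.normal(-sigma**2 / 2, sigma))
    return float(signal * eps)
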