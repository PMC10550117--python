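import numpy as np
import pytest

from lucflow.fcs_io import EventTable
from lucflow.gating import GateConfig
from lucflow.simulate import CHANNELS, CHANNEL_ROLES, SyntheticTubeSpec, simulate_tube


@pytest.fixture
def default_config():
    return GateConfig()


@pytest.fixture
def simulated_tube():
    """A clean 20k-event tube with known generative parameters."""
    spec = SyntheticTubeSpec(n_events=20_000, expression_level=5_000.0, seed=1234,
                             tube_id="fixture")
    table, truth = simulate_tube(spec)
    return table, truth, spec


def make_table(events: np.ndarray, tube_id: str = "t") -> EventTable:
    """EventTable over the simulator's standard six channels."""
    return EventTable(
        tube_id=tube_id,
        channel_names=list(CHANNELS),
        channel_roles=dict(CHANNEL_ROLES),
        events=events,
    )


def binomial_99_interval(p: float, n: int) -> tuple[float, float]:
    """Normal-approximation 99% interval for a binomial fraction."""
    half = 2.5758 * np.sqrt(p * (1 - p) / n)
    return p - half, p + half
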