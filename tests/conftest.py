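import numpy as np
import pytest

from gazesync.simulate import (
    GazeTimeline,
    SimulationConfig,
    simulate_dyad,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def timeline_from_spans(role, spans, frame_rate=50.0):
    """Build a GazeTimeline from (state, seconds) spans."""
    states = []
    for state, dur in spans:
        states += [state] * int(round(dur * frame_rate))
    return GazeTimeline(role, np.array(states), frame_rate)


@pytest.fixture(scope="session")
def small_dyad():
    """One 60-s dyad at full realism, shared across read-only tests."""
    return simulate_dyad(SimulationConfig(seed=42, duration=60.0))


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, oscillator-free config for exact-identity checks."""
    return SimulationConfig(
        seed=0,
        duration=30.0,
        noise_amplitude=0.0,
        oscillators=(),
        reset_strength=0.0,
    )
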