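import numpy as np
import pytest

from circatissue import (
    ClockParameters,
    extract_rhythm_descriptors,
    simulate_clock,
)


@pytest.fixture(scope="session")
def default_clock():
    """Limit cycle of the default (liver-like) parameter set."""
    return simulate_clock(ClockParameters(), t_end=480.0, dt=0.05)


@pytest.fixture(scope="session")
def default_descriptors(default_clock):
    desc = extract_rhythm_descriptors(default_clock)
    assert desc.oscillation_sustained
    return desc


@pytest.fixture(scope="session")
def cosine_trajectory():
    """All five species as a pure 24 h cosine (mean 1, amplitude 0.5)."""
    from circatissue import GENES, Trajectory

    dt = 0.05
    t = np.arange(0, 480 + dt / 2, dt)
    x = 1.0 + 0.5 * np.cos(2 * np.pi * t / 24.0)
    values = np.tile(x[:, None], (1, 5))
    return Trajectory(t, values, GENES, dt, {"transient": 240.0})
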