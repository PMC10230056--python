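import numpy as np
import pytest

from synergait import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def short_recording():
    """A 6 s default-condition walking simulation shared across tests."""
    return simulate_recording(SimConfig(duration_s=6.0, seed=11))


@pytest.fixture(scope="session")
def exact_recording():
    """Zero cycle-variance simulation: every event at its nominal fraction."""
    return simulate_recording(SimConfig(duration_s=6.0, cycle_sd_s=0.0, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
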