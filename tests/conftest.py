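import numpy as np
import pytest

from noddax.scheme import AcquisitionScheme
from noddax.simulate import SimulationConfig, fibonacci_directions, make_scheme


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def high_b_scheme(default_config):
    """The simulated 3-shell high-b protocol (6 b0 + 3 x 64 directions)."""
    return make_scheme(default_config)


@pytest.fixture(scope="session")
def tiny_scheme():
    """A nine-volume scheme for oracle comparisons (1 b0 + 4 dirs x 2 shells)."""
    rng = np.random.default_rng(7)
    g = fibonacci_directions(4, rng)
    b = np.concatenate([[0.0], np.full(4, 6.75), np.full(4, 13.5)])
    gs = np.vstack([[0, 0, 1.0], g, fibonacci_directions(4, rng)])
    return AcquisitionScheme(b=b, g=gs)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
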