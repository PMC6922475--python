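import numpy as np
import pytest

from kinetrend.grid import human_grid, make_time_grid, mouse_grid


@pytest.fixture(scope="session")
def mouse():
    return mouse_grid()


@pytest.fixture(scope="session")
def human():
    return human_grid()


@pytest.fixture(scope="session")
def small_grid():
    """30-point 10-minute grid: big enough to fit, small enough to enumerate."""
    return make_time_grid(10, 290)


@pytest.fixture
def rng():
    return np.random.default_rng(20191209)
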