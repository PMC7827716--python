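import numpy as np
import pytest

from pamcr import make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def nir_grid():
    """The full acquisition grid: 680-970 nm at 2 nm steps."""
    return make_grid(680, 970, 2)


@pytest.fixture(scope="session")
def small_grid():
    """A short grid for cheap factorization tests."""
    return make_grid(680, 700, 2)
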