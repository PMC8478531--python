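import numpy as np
import pytest

import matepred as mp


@pytest.fixture
def k_half():
    """Dimensionless parameters with a coexistence state (k2 < 1)."""
    return mp.DimensionlessParams(k1=1.0, k2=0.5)


@pytest.fixture
def grid900():
    return mp.make_grid(900.0, 64)


@pytest.fixture
def small_grid():
    return mp.make_grid(2.0 * np.pi, 16)


@pytest.fixture
def rng():
    return np.random.default_rng(20210921)
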