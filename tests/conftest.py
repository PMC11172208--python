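import numpy as np
import pytest

from fraccs import OptimizerConfig, SearchBounds


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_bounds_3():
    return SearchBounds.unit(3)


@pytest.fixture
def fast_config():
    """Small-budget optimizer config for cheap structural tests."""
    return OptimizerConfig(n_nests=8, n_cuckoos_per_iter=5, max_iter=20, seed=0)


class ForcedUniform:
    """Minimal rng stand-in whose uniform() returns preset values."""

    def __init__(self, value: float):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


@pytest.fixture
def forced_uniform():
    return ForcedUniform
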