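import numpy as np
import pytest

from argstitch import simulate_coalescent


@pytest.fixture(scope="session")
def small_dataset():
    """20 haploids over 200 kb: the workhorse fixture."""
    return simulate_coalescent(20, 2e5, seed=101)


@pytest.fixture(scope="session")
def pair_dataset():
    """Two haploids over 100 kb (single-pair geometry)."""
    return simulate_coalescent(2, 1e5, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
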