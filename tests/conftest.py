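import numpy as np
import pytest

from minimaxkl import DiscreteDistribution


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def random_simplex(rng):
    """Factory for random valid probability vectors."""

    def make(m: int, concentration: float = 1.0) -> DiscreteDistribution:
        return DiscreteDistribution(rng.dirichlet(np.full(m, concentration)))

    return make
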