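import numpy as np
import pytest

from fgmsim.landscape import SelectionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def random_spd(rng, n, scale=10.0):
    """Random symmetric positive-definite selection matrix."""
    A = rng.normal(size=(n, n))
    return SelectionMatrix(A @ A.T + scale * np.eye(n))


@pytest.fixture
def random_spd_factory(rng):
    return lambda n=2, scale=10.0: random_spd(rng, n, scale)
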