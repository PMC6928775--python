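import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_pair(rng):
    """A random small integer-valued (reference, stream) pair."""
    N = int(rng.integers(1, 7))
    M = int(rng.integers(N, 11))
    x = rng.integers(0, 5, size=(1, N)).astype(float)
    y = rng.integers(0, 5, size=(1, M)).astype(float)
    return x, y
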