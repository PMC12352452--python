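import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tensor_123():
    """2x2x2 tensor whose 1-based entry (i,j,k) is i + 2(j-1) + 4(k-1)."""
    return np.arange(1.0, 9.0).reshape(2, 2, 2, order="F")


@pytest.fixture
def small_tensor(rng):
    return rng.standard_normal((3, 4, 5))
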