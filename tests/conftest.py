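import numpy as np
import pytest

from ttshift import Series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gaussian_pair(rng):
    """Two independent iid Gaussian series of length 200."""
    return Series(rng.normal(size=200), label="x"), Series(
        rng.normal(size=200), label="y"
    )
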