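import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_mv_pairs(rng):
    """1000 random multivector pairs for algebra identity checks."""
    return rng.standard_normal((1000, 2, 4))
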