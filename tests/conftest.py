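import numpy as np
import pytest

from ctnlm import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_int_volume(rng):
    """7x7x7 integer-valued volume for exact SSD oracle comparisons."""
    return Volume(rng.integers(0, 64, (7, 7, 7)).astype(np.float64))


@pytest.fixture
def small_float_volume(rng):
    """7x7x7 float volume for SSD tolerance comparisons."""
    return Volume(rng.normal(100.0, 25.0, (7, 7, 7)))
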