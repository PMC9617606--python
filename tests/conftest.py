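import numpy as np
import pytest

from isotomo.tomio import Tomogram


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_volume(rng):
    return rng.standard_normal((32, 32, 32)).astype(np.float32)


@pytest.fixture
def random_tomogram(rng):
    data = rng.standard_normal((40, 48, 56)).astype(np.float32)
    return Tomogram(data, pixel_size=10.8, name="synthetic_random")
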