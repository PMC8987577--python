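import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape=(24, 24), p=0.4):
    return rng.random(shape) < p
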