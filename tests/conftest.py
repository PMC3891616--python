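import numpy as np
import pytest

from pfclust import HyperParams, load_x12


@pytest.fixture
def x12():
    return load_x12()


@pytest.fixture
def params():
    return HyperParams(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
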