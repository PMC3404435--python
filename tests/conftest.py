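import numpy as np
import pytest

from ctvisnet.geometry import make_object_library
from ctvisnet.stimuli import pentagon_layout


@pytest.fixture(scope="session")
def library():
    return make_object_library(seed=0)


@pytest.fixture(scope="session")
def layout64():
    return pentagon_layout(64)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
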