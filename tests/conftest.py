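import numpy as np
import pytest

from perisim import IOWA_HMP, OCTOPUS900, generate_10_2


@pytest.fixture
def octopus():
    return OCTOPUS900


@pytest.fixture
def hmp():
    return IOWA_HMP


@pytest.fixture
def grid():
    return generate_10_2()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
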