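import numpy as np
import pytest

from fretshift.photophysics import PhotophysicsParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def photo():
    return PhotophysicsParams()  # k_D=0.25/ns, k_A=0.5/ns, R0=40 A
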