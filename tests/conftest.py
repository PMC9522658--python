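import numpy as np
import pytest

from lysoscan import healthy_s1
from lysoscan.decompose import decompose, select_rank
from lysoscan.simulate import simulate_waveform


@pytest.fixture(scope="session")
def healthy_waveform():
    """Default healthy-S1 waveform at the standard noise level, fixed seed."""
    return simulate_waveform(healthy_s1(seed=0))


@pytest.fixture(scope="session")
def healthy_result(healthy_waveform):
    """Decomposed healthy-S1 waveform with rank selected at defaults."""
    result = decompose(healthy_waveform)
    select_rank(result)
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
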