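import numpy as np
import pytest
from hypothesis import settings

from ergkit import FlashProtocol, WaveformParams

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture
def protocol() -> FlashProtocol:
    return FlashProtocol()


@pytest.fixture
def noiseless_params() -> WaveformParams:
    return WaveformParams(noise_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
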