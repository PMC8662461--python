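import numpy as np
import pytest

from ovitrack import ArenaConfig, RadarConfig


@pytest.fixture
def arena():
    return ArenaConfig()


@pytest.fixture
def radar():
    return RadarConfig()


@pytest.fixture
def quiet_radar():
    """Indoor radar with the noise switched off (deterministic synthesis)."""
    return RadarConfig(noise_sigma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
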