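import numpy as np
import pytest

from satcpg import demography as dem


@pytest.fixture(scope="session")
def eur_model():
    return dem.build_preset("eur_recent10M")


@pytest.fixture(scope="session")
def small_constant_model():
    """Constant N=1000 with a short span: cheap enough for many replicates."""
    return dem.build_preset("constant", N=1000, duration=4000, burn_in_multiplier=8)


@pytest.fixture(scope="session")
def tiny_model():
    """Very small constant model for smoke tests where realism is irrelevant."""
    return dem.build_preset("constant", N=100, duration=200, burn_in_multiplier=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
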