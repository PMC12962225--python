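import numpy as np
import pytest

from wfsrecon import (EchoTimes, PhantomConfig, SpectralModel, make_phantom)


@pytest.fixture(scope="session")
def model():
    return SpectralModel()


@pytest.fixture(scope="session")
def times():
    return EchoTimes.symmetric()


@pytest.fixture(scope="session")
def small_cfg():
    return PhantomConfig(shape=(48, 48), n_coils=4, seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_cfg):
    return make_phantom(small_cfg)


@pytest.fixture(scope="session")
def mid_cfg():
    return PhantomConfig(shape=(64, 64), n_coils=4, seed=3)


@pytest.fixture(scope="session")
def mid_phantom(mid_cfg):
    return make_phantom(mid_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
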