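import numpy as np
import pytest
from hypothesis import settings

from wgdkit.phylo.model import poisson_model
from wgdkit.scenario import default_scenario

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def scenario():
    return default_scenario()


@pytest.fixture(scope="session")
def model():
    return poisson_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
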