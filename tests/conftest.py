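import numpy as np
import pytest

import phagemix as pm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cross_matrix():
    return pm.load_fixture("cross_matrix")


@pytest.fixture(scope="session")
def phage_panel():
    return pm.load_fixture("phages")


@pytest.fixture(scope="session")
def stability_series():
    return pm.load_fixture("stability")


@pytest.fixture
def config():
    return pm.SimulationConfig(seed=7)
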