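import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from flashlysis.reaction_network import default_network
from flashlysis.synthetic_fixtures import FixtureSpec, synth_joint_distribution


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def joint_dist():
    return synth_joint_distribution(FixtureSpec())
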