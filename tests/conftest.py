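import numpy as np
import pytest

from mutenc.simulate import SimParams, make_toy_structure
from mutenc.structures import build_contact_graph


@pytest.fixture(scope="session")
def toy_structure():
    """Length-20 globular toy protein used across training-level tests."""
    return make_toy_structure(20, seed=7)


@pytest.fixture(scope="session")
def toy_graph(toy_structure):
    return build_contact_graph(toy_structure)


@pytest.fixture(scope="session")
def sim_params():
    return SimParams.random(seed=7)


@pytest.fixture(scope="session")
def additive_params():
    """Simulator parameters with the pair coupling J zeroed: exactly additive."""
    return SimParams.random(seed=7, coupling_scale=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
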