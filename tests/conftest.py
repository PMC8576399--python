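import numpy as np
import pytest

import igsim
from igsim import fixtures


@pytest.fixture(scope="session")
def toy_db():
    return igsim.generate_toy_germline(n_v=48, n_d=5, n_j=6, v_length=296, seed=1)


@pytest.fixture(scope="session")
def junction_model():
    return fixtures.default_junction_model()


@pytest.fixture(scope="session")
def substitution_model():
    return fixtures.default_substitution_model()


@pytest.fixture(scope="session")
def mutability_model():
    return fixtures.default_mutability_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
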