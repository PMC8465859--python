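import numpy as np
import pytest

from nesskit import ness
from nesskit.fixtures import make_fixture


@pytest.fixture(scope="session")
def lorenz_laplace():
    """Laplace exemplar of the (time-dilated) stochastic Lorenz system."""
    return make_fixture("lorenz-laplace", seed=1)


@pytest.fixture(scope="session")
def coupled_laplace():
    """Laplace exemplar of the coupled Lorenz pair."""
    return make_fixture("coupled-laplace", seed=1)


@pytest.fixture(scope="session")
def lorenz_gaussian(lorenz_laplace):
    return ness.gaussian_from_potential(lorenz_laplace.params)


@pytest.fixture(scope="session")
def coupled_gaussian(coupled_laplace):
    return ness.gaussian_from_potential(coupled_laplace.params)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
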