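import numpy as np
import pytest

import rlca


@pytest.fixture(scope="session")
def dicho_design():
    return rlca.fixture_design("dichotomous_4class")


@pytest.fixture(scope="session")
def poly_design():
    return rlca.fixture_design("polytomous_4class")


@pytest.fixture(scope="session")
def dicho_data(dicho_design):
    """N=1000 draw from the dichotomous design (fixed seed)."""
    data, membership = rlca.simulate(dicho_design, 1000, seed=1)
    return data, membership


@pytest.fixture(scope="session")
def poly_data(poly_design):
    data, membership = rlca.simulate(poly_design, 1000, seed=1)
    return data, membership


@pytest.fixture(scope="session")
def dicho_base_fit(dicho_data):
    """Unpenalized 4-class fit on the shared dichotomous dataset."""
    data, _ = dicho_data
    return rlca.fit(data, 4, spec=None, n_starts=10, seed=11)


@pytest.fixture(scope="session")
def poly_base_fit(poly_data):
    data, _ = poly_data
    return rlca.fit(data, 4, spec=None, n_starts=10, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
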