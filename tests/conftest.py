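import numpy as np
import pytest

from refclust import PhantomParams, make_parcellation, simulate_cohort


@pytest.fixture(scope="session")
def desk_params():
    """Desk-scale phantom with the strong core deficit used for recovery checks."""
    return PhantomParams(shape=(24, 24, 24), hypometabolism_factor=0.8)


@pytest.fixture(scope="session")
def desk_truth(desk_params):
    return make_parcellation(desk_params)


@pytest.fixture(scope="session")
def desk_cohort(desk_params):
    """10v10 cohort on a 24^3 grid; session-scoped because simulation is reused."""
    return simulate_cohort(desk_params, 10, 10, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
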