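import numpy as np
import pytest

from dmaxent.island import island_model
from dmaxent.ou import ou_model


@pytest.fixture(scope="session")
def ou():
    """OU model at the reference noise magnitude sigma0 = 0.1."""
    return ou_model(0.1)


@pytest.fixture(scope="session")
def island():
    return island_model()


@pytest.fixture(scope="session")
def ou_step():
    """OU step-change reference scenario: three stationary starts relaxing
    towards (mu, beta) = (1, 0.7) with sigma0 = 0.1."""
    return {
        "mu_inf": 1.0,
        "beta_inf": 0.7,
        "sigma0": 0.1,
        "initials": [(1.2, 0.7), (0.6, 0.5), (0.1, 0.45)],
    }


@pytest.fixture(scope="session")
def island_step():
    """Island step-change reference scenario (stationary start, abrupt
    change of all three ecological forces at t = 0)."""
    return {
        "alpha0": np.array([0.05, 0.005, 1.0]),
        "alpha1": np.array([0.1, 0.002, 3.0]),
    }
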