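import numpy as np
import pytest
from hypothesis import settings

from enrichtrial import DesignConfig, Prior

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture
def config():
    """Reference design: equal subpopulations, interim at half the sample,
    information calibrated for 90% power at effect 10."""
    return DesignConfig(lambda_frac=0.5, tau=0.5, alpha=0.025, info_total=0.105)


@pytest.fixture
def config_n():
    """Same design parameterised by (n, sigma)."""
    return DesignConfig(lambda_frac=0.5, tau=0.5, alpha=0.025, n_total=264, sigma=25)


@pytest.fixture
def point_prior():
    return Prior.point(10.0, 2.0)


@pytest.fixture
def bvn_prior():
    return Prior.bvn(10.0, 2.0, 25.0, 25.0, 0.75)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
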