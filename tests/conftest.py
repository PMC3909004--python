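import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abxward import EpiParams, PharmacodynamicParams

settings.register_profile(
    "ci",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def epi() -> EpiParams:
    """Standard epidemiological parameters (beta=1, sigma=0.25, gamma=0.25, c=0.1)."""
    return EpiParams()


@pytest.fixture(scope="session")
def pdp() -> PharmacodynamicParams:
    """Standard dose-response shape (phi_max=0.25, phi_min=-0.25, k=1)."""
    return PharmacodynamicParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
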