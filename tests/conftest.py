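import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sbecld as sb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_params() -> sb.EnzymeSetParams:
    """Enzyme-set (i) parameters fitted to Nipponbare endosperm amylopectin."""
    return sb.EnzymeSetParams(beta=1.4, x_min=6, x_0=7)


@pytest.fixture(scope="session")
def reference_solution(reference_params) -> sb.SteadyStateSolution:
    return sb.steady_state_cld(reference_params)


@pytest.fixture(scope="session")
def wt_spec() -> sb.SBESpecificity:
    """Wild-type maize SBEIIa: both fragment minima 6, short-transfer bias."""
    return sb.SBESpecificity(x_min=6, x_0=6, cut_kernel=sb.geometric_kernel(0.45))


@pytest.fixture(scope="session")
def r456k_spec() -> sb.SBESpecificity:
    """R456K: fragment minima relaxed to 2, donor floor kept at 12."""
    return sb.SBESpecificity(
        x_min=2, x_0=2, cut_kernel=sb.uniform_kernel, min_donor_dp=12
    )


@pytest.fixture(scope="session")
def amylopectin_substrate(reference_params) -> sb.ChainPopulation:
    """Amylopectin-like population sampled from the biosynthesis model."""
    return sb.make_amylopectin_substrate(reference_params, n_chains=100_000, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
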