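import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import prsprob as pp

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def cases_eq():
    """Case moments for the canonical equal-variance worked example."""
    return pp.GroupMoments("cases", 0.5, 1.0)


@pytest.fixture
def noncases_eq():
    return pp.GroupMoments("noncases", 0.0, 1.0)


@pytest.fixture(scope="session")
def paper_scale_report():
    """Full-scale polygenic validation run, shared by the tests that need it.

    10,000 cases + 10,000 controls, 10,039 independent SNPs (39 strong, the
    rest weak), prevalence 0.10.
    """
    config = pp.prs_like_scenario(10_000, 10_000, seed=1)
    return pp.validate(config, K=0.1)


@pytest.fixture(scope="session")
def ors_scale_report():
    """Oligogenic (39 strong SNPs) validation at the same sample size."""
    config = pp.ors_like_scenario(10_000, 10_000, seed=1)
    return pp.validate(config, K=0.1)


def random_moments(rng: np.random.Generator, equal_variance: bool = False):
    """Draw a random valid (cases, noncases, K) triple for property checks."""
    m0 = rng.uniform(-1, 1)
    m1 = m0 + rng.uniform(0.05, 1.5)
    v0 = rng.uniform(0.2, 3.0)
    v1 = v0 if equal_variance else rng.uniform(0.2, 3.0)
    K = rng.uniform(0.01, 0.5)
    return (
        pp.GroupMoments("cases", m1, v1),
        pp.GroupMoments("noncases", m0, v0),
        K,
    )
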