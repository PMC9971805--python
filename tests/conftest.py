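import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import psmcea as m
from psmcea.distributions import DistSpec

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def base_config():
    return m.base_case_config()


@pytest.fixture(scope="session")
def base_result(base_config):
    return m.run_base_case(base_config)


@pytest.fixture(scope="session")
def psa_samples(base_config):
    """The fixture PSA: 1000 draws at the configuration's default seed."""
    return m.psa(base_config)


def random_dist(rng: np.random.Generator) -> DistSpec:
    """A random valid distribution with parameters in plausible ranges."""
    family = rng.choice(
        ["exponential", "weibull", "gamma", "gompertz", "lognormal", "loglogistic"]
    )
    if family == "exponential":
        params = (rng.uniform(0.02, 0.4),)
    elif family == "gompertz":
        params = (rng.uniform(0.01, 0.25), rng.uniform(0.005, 0.15))
    elif family == "lognormal":
        params = (rng.uniform(0.5, 3.5), rng.uniform(0.3, 1.4))
    else:  # weibull / gamma / loglogistic: shape, scale
        params = (rng.uniform(0.5, 4.0), rng.uniform(2.0, 40.0))
    return DistSpec(family, params)
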