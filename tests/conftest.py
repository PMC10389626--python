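import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import condsurv as cs
from condsurv.encoding import EncodingConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def published():
    return cs.published_parameters()


@pytest.fixture(scope="session")
def enc65():
    """Encoding centered exactly at the example patient's age, so the
    example dot products are exact."""
    return EncodingConfig(age_center=65.0, age_scale=10.0)


@pytest.fixture(scope="session")
def example_record():
    return cs.EXAMPLE_PROFILE


@pytest.fixture(scope="session")
def example_design(example_record, enc65):
    return cs.encode_design(example_record, enc65)


@pytest.fixture(scope="session")
def small_cohort(published):
    """A small derivation-like synthetic cohort used across tests."""
    return cs.simulate_cohort(cs.SimulationConfig(n=400, seed=42))


def random_monotone_params(rng, dims=(1, 1, 1, 1, 1), family="loglogistic"):
    """Random coefficient set in the monotone-S4 regime."""
    a = rng.normal(0, 0.8, dims[0])
    e = rng.normal(1.5, 0.5, dims[1])
    p = np.concatenate([[-rng.uniform(0.3, 1.5)], rng.normal(0, 0.2, dims[2] - 1)])
    g = rng.normal(-1.0, 0.7, dims[3])
    r = np.concatenate([[-rng.uniform(0.05, 0.6)], rng.normal(0, 0.1, dims[4] - 1)])
    return cs.ModelParameters(a, e, p, g, r, family=family)


def random_design(rng, dims=(1, 1, 1, 1, 1)):
    vecs = []
    for k in dims:
        v = rng.normal(0, 1, k)
        v[0] = 1.0
        vecs.append(v)
    return cs.DesignVectors(*vecs)
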