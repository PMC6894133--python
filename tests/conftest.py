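import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hecohort as hc
from hecohort.he.params import derive_params

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def schoolbook_negacyclic(a, b, n, q):
    """O(n^2) negacyclic product oracle over centered representatives."""
    c = [0] * n
    half = q // 2
    for i, ai in enumerate(a):
        ai = ai - q if ai > half else ai
        for j, bj in enumerate(b):
            bj = bj - q if bj > half else bj
            k = i + j
            if k < n:
                c[k] += ai * bj
            else:
                c[k - n] -= ai * bj
    return [x % q for x in c]


@pytest.fixture(scope="session")
def add_params():
    """Small depth-0 parameter set (counting-style workloads)."""
    return derive_params(128, max_value=50, mult_depth=0)


@pytest.fixture(scope="session")
def mult_params():
    """Small depth-1 parameter set (product workloads)."""
    return derive_params(128, max_value=100, mult_depth=1)


@pytest.fixture(scope="session")
def add_keys(add_params):
    return hc.keygen(add_params, np.random.default_rng(1234))


@pytest.fixture(scope="session")
def mult_keys(mult_params):
    return hc.keygen(mult_params, np.random.default_rng(5678))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def tiny_cohort():
    return hc.simulate_cohort(hc.CohortParams(n_patients=40, seed=7))
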