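import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bsamap as bm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_population():
    """A modest F2 with a causal locus, reused across read-only tests."""
    config = bm.SimConfig(seed=11, n_f2=400, n_snps=2_000)
    return bm.simulate_f2(config)


@pytest.fixture(scope="session")
def pool_sites(small_population):
    bulks = bm.make_bulks(small_population)
    return bm.simulate_pools(small_population, bulks)


@pytest.fixture(scope="session")
def bound_simulator():
    """Session-wide memoized null-bound simulator (bulks of 50)."""
    return bm.NullBoundSimulator(bulk_size=50, n_sim=10_000, seed=77)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
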