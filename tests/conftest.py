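import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from amoalink import SimulationParams, simulate_queries, simulate_reference_set

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams(seed=7)


@pytest.fixture(scope="session")
def sim_db(default_params):
    """A 4-order x 3-clade x 4-ref synthetic paired database (seed 7)."""
    rng = np.random.default_rng(default_params.seed)
    db, ancestors = simulate_reference_set(default_params, rng)
    return db


@pytest.fixture(scope="session")
def sim_queries(sim_db, default_params):
    rng = np.random.default_rng(1234)
    return simulate_queries(sim_db, default_params, 60, rng)
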