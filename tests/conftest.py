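import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def counterexample_dataset():
    """Default empty-feature simulation, fixed seed, relative abundances."""
    from clrsparse import SimulationConfig, simulate_counterexample

    return simulate_counterexample(SimulationConfig(seed=7))


@pytest.fixture
def small_cohort():
    """Small Dirichlet-multinomial cohort with a singleton taxon."""
    from clrsparse import CohortConfig, simulate_cohort

    return simulate_cohort(
        CohortConfig(n_per_group=15, n_taxa=30, depth=5_000, seed=3)
    )
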