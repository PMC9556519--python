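import numpy as np
import pytest

from hybridqc import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 200-participant cohort for cheap structural tests."""
    return syn.generate_cohort(200, seed=1234)


@pytest.fixture(scope="session")
def small_metrics(small_cohort):
    return syn.generate_metrics(small_cohort, seed=1234)


@pytest.fixture(scope="session")
def small_experts(small_cohort):
    return syn.simulate_expert_ratings(small_cohort, seed=1234)


@pytest.fixture(scope="session")
def small_community(small_cohort):
    return syn.simulate_community_ratings(small_cohort, seed=1234)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)
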