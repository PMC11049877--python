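import pytest

from rossig.simdata import SimConfig, simulate_cohorts

# small but non-trivial world shared by read-only tests
SMALL_CONFIG = SimConfig(
    n_genes=300,
    n_samples_discovery=80,
    n_samples_validation=50,
    n_planted=60,
    ros_list_size=50,
    ros_overlap_with_planted=20,
    seed=11,
)


@pytest.fixture(scope="session")
def small_world():
    """(expr_disc, expr_val, meta, truth) from a seeded 300-gene simulation."""
    return simulate_cohorts(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_config():
    return SMALL_CONFIG
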