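import numpy as np
import pytest

from crowdrate import ExperimentConfig, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20230128)


@pytest.fixture(scope="session")
def small_config():
    """A down-scaled experiment: 2 groups/condition, 10 subjects, 4 messages."""
    return ExperimentConfig(
        n_segregated_liberal_first=2,
        n_segregated_conservative_first=2,
        n_integrated=2,
        n_independent=2,
        group_size=10,
        n_per_cell=1,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_decisions(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def medium_decisions():
    """Enough independent-condition data for stable difficulty estimates."""
    config = ExperimentConfig(
        n_segregated_liberal_first=4,
        n_segregated_conservative_first=4,
        n_integrated=4,
        n_independent=8,
        group_size=20,
        n_per_cell=2,
        seed=7,
    )
    return generate_experiment(config)
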