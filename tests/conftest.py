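import numpy as np
import pytest

from cyclesim import SimulationConfig, simulate_cohort
from cyclesim.features import feature_table


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_eumenorrheic=20, n_pcos=10, cycles_per_subject=2,
                            master_seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return feature_table(small_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def noise_free(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every observation-noise SD set to zero."""
    import dataclasses
    return dataclasses.replace(config, noise_sd={k: 0.0 for k in config.noise_sd})
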