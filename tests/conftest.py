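import numpy as np
import pandas as pd
import pytest

from sigforge import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-scale study: enough genes for BH to behave, small cohorts."""
    return SimulationConfig(
        n_genes=600,
        n_core_hypoxia_genes=30,
        n_partial_hypoxia_genes=30,
        cohort_sizes=(120, 80),
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
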