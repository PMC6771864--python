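import logging

import numpy as np
import pytest

from prsdissect.synthio import SimConfig, simulate_study

logging.getLogger("prsdissect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A reduced study: 300 target / 800 discovery subjects, 120 variants."""
    return SimConfig(
        seed=7,
        n_target=300,
        n_discovery=800,
        n_blocks=12,
        snps_per_block=10,
        n_causal=20,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
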