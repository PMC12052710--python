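import numpy as np
import pytest

from fibermwas import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A fast cohort: 60 animals, 40 genera, shallow depths."""
    return SimConfig(
        n_samples=60,
        n_genera=40,
        n_causal_quant=2,
        n_causal_binary=1,
        depth_range=(2000, 4000),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
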