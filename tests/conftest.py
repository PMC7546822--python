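import numpy as np
import pytest

from neoperf import SimulationConfig, make_atlas, simulate_cohort


@pytest.fixture(scope="session")
def default_atlas():
    return make_atlas(SimulationConfig())


@pytest.fixture(scope="session")
def zero_noise_config():
    """Small noiseless cohort: quantification must invert exactly."""
    return SimulationConfig(
        noise_sd=0.0,
        subject_cv=0.0,
        outlier_rate=0.0,
        groups=(("control", 2), ("hie_neg", 2), ("hie_pos", 2)),
        n_pairs=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def zero_noise_cohort(zero_noise_config):
    return simulate_cohort(zero_noise_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
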