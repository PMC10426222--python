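import numpy as np
import pytest

from angerppg.pipeline import run_pipeline
from angerppg.synthetic_cohort import GeneratorConfig, ScheduleConfig, generate_cohort
from angerppg.tsfeatures import FeatureBankConfig


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Four participants (one TBI), compact protocol, no motion artifacts."""
    return GeneratorConfig(
        n_participants=4,
        tbi_fraction=0.25,
        motion_gain=0.0,
        schedule=ScheduleConfig.compact(),
        seed=101,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_pipeline(small_config):
    """Windows + raw and normalized feature matrices for the small cohort."""
    return run_pipeline(generator_config=small_config, denoise=False)


@pytest.fixture(scope="session")
def one_session(small_cohort):
    return small_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
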