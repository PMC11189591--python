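import numpy as np
import pytest

from prefobs.ddm import DDMParams
from prefobs.synthetic import (
    StudyConfig,
    generate_dictator_dataset,
    make_design,
    sample_dictators,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def study_config():
    return StudyConfig()


@pytest.fixture(scope="session")
def design(study_config):
    """The full 165-trial Dictator-Game design under a fixed seed."""
    return make_design(study_config, np.random.default_rng(7))


@pytest.fixture(scope="session")
def dictators(study_config):
    return sample_dictators(study_config, np.random.default_rng(11))


@pytest.fixture(scope="session")
def dictator_dataset(design, dictators):
    """One simulated dictator (P ~ 0.3) with 165 DDM decisions."""
    d = dictators[4]
    df = generate_dictator_dataset(d, design, np.random.default_rng(23))
    return d, df


@pytest.fixture(scope="session")
def reference_ddm():
    return DDMParams(boundary=2.0, ndt=0.3, drift_scale=5.0)
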