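import numpy as np
import pytest
from hypothesis import settings

from ppsc.simulate import FEATURE_COLUMNS, GeneratorConfig, generate_cohort

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def small_cohort():
    """A clean 250-patient synthetic cohort shared across tests."""
    return generate_cohort(GeneratorConfig(n_patients=250, seed=11))


@pytest.fixture(scope="session")
def cohort_Xy(small_cohort):
    X = small_cohort[list(FEATURE_COLUMNS)].astype(float)
    y = small_cohort["recovered"].astype(int).to_numpy()
    return X, y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
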