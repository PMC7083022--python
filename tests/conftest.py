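import numpy as np
import pytest
from hypothesis import settings

from genassoc import datasets

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def markers():
    return datasets.study_markers()


@pytest.fixture(scope="session")
def study_cohort():
    return datasets.study_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)
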