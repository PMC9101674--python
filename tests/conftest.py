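import numpy as np
import pytest
from hypothesis import settings

from hingepoint import datagen

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec():
    return datagen.default_cohort_spec()


@pytest.fixture(scope="session")
def cohort(default_spec):
    """One default synthetic cohort (357 patients), fixed seed."""
    return datagen.simulate_cohort(default_spec, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
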