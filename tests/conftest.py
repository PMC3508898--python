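import numpy as np
import pytest
from hypothesis import settings

from ggamma.synthetic_data import Cohort, SynthConfig, make_cohort

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """5 sequences per structural type, fixed seed."""
    return make_cohort(SynthConfig(seed=11, n_per_type={"A": 5, "B": 5, "C": 5}))


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(seed=11, n_per_type={"A": 5, "B": 5, "C": 5})


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
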