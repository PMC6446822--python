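import numpy as np
import pytest

from helpers import cohort_of
from ridlsim.lifecycle import FEMALE, MALE


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rng_factory():
    def make(seed: int = 12345) -> np.random.Generator:
        return np.random.default_rng(seed)

    return make


@pytest.fixture
def fixed_rr_pair():
    """One RR/ww female and one RR/ww male."""
    return cohort_of((2, 0, FEMALE, 1), (2, 0, MALE, 1))
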