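import numpy as np
import pytest
from hypothesis import settings

from lcgate.datasets import (
    FULL_TRIAL_MAJOR_ATTEMPTS,
    FULL_TRIAL_N_ATTEMPTS,
    load_sample_attempts,
)

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sample_records():
    """The bundled 18-attempt training-log excerpt."""
    return load_sample_attempts()


@pytest.fixture(scope="session")
def full_trial_indicators():
    """132-attempt major-mistake indicator reconstruction of the full trial."""
    ind = np.zeros(FULL_TRIAL_N_ATTEMPTS, dtype=np.int64)
    ind[np.array(FULL_TRIAL_MAJOR_ATTEMPTS) - 1] = 1
    return ind
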