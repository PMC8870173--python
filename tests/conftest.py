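import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tacsfx.simulate import EegSimConfig, MepSimConfig, generate_eeg


@pytest.fixture
def rng():
    return np.random.default_rng(20220131)


@pytest.fixture(scope="session")
def quiet_eeg():
    """A short artifact-free recording with the default oscillations."""
    return generate_eeg(
        EegSimConfig(duration_s=20.0, blink_rate_per_min=0.0, seed=7)
    )


@pytest.fixture(scope="session")
def default_mep_config():
    return MepSimConfig(seed=3)
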