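import numpy as np
import pytest

from tugtmg.synth import NoiseModel, TugProfile
from tugtmg.tug import BandConfig


@pytest.fixture
def band() -> BandConfig:
    return BandConfig()


@pytest.fixture
def canonical_profile() -> TugProfile:
    """The cohort-mean subtask durations (sums to a 20.29 s test)."""
    return TugProfile(
        sit_up_s=4.51, walk_forward_s=3.78, turn_s=3.00, walk_back_s=4.41, sit_down_s=4.59
    )


@pytest.fixture
def study_noise() -> NoiseModel:
    """The sensor's nominal degradation: 3 cm noise and 3 cm quantization."""
    return NoiseModel(quantization_m=0.03, gaussian_sd_m=0.03, seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20211006)
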