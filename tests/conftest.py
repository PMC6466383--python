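import numpy as np
import pytest

from metcalib import ArchetypeSpec, generate_raw_recording
from metcalib.simulate import DEFAULT_ACTIVITY_PROFILES


@pytest.fixture(scope="session")
def locomotor_recording():
    return generate_raw_recording(ArchetypeSpec("locomotor", seed=7, duration_s=120.0))


@pytest.fixture(scope="session")
def sedentary_recording():
    return generate_raw_recording(ArchetypeSpec("sedentary_play", seed=7, duration_s=120.0))


@pytest.fixture(scope="session")
def still_recording():
    return generate_raw_recording(
        ArchetypeSpec("still", seed=7, duration_s=60.0), epoch_length_s=60.0
    )


@pytest.fixture(scope="session")
def activity_profiles():
    return DEFAULT_ACTIVITY_PROFILES


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
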