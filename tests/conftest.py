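import numpy as np
import pytest

from gaitcast.io_preprocess import SensorRecording, canonical_channels
from gaitcast.synthetic_data import SyntheticGaitSpec, generate_subject


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng) -> SensorRecording:
    """A 200-sample, 63-channel recording with valid footswitches."""
    M = 200
    samples = rng.standard_normal((M, 63))
    fsw = (rng.uniform(size=(M, 8)) < 0.5).astype(int)
    return SensorRecording(
        subject_id="T00", speed_level=1, sample_rate=50.0,
        samples=samples, channels=canonical_channels(), footswitches=fsw,
    )


@pytest.fixture(scope="session")
def synthetic_recording() -> SensorRecording:
    """30 s of clean synthetic gait at 50 Hz (one subject, middle speed)."""
    spec = SyntheticGaitSpec(n_subjects=1, duration=30.0, noise_sd=0.05, seed=7)
    return generate_subject(spec, 0, 3)
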