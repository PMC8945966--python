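import numpy as np
import pytest

from ecg2bp.labeling import label_frames
from ecg2bp.preprocess import preprocess_record
from ecg2bp.synth import SyntheticConfig, simulate_record


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free constant-BP generator config: every cycle is exactly 120/80."""
    return SyntheticConfig(
        duration_s=20.0, hr_bpm=72.0, hr_sd=0.0, bp_drift=0.0,
        coupling=None, coupling_noise_sd=0.0, pulse_pressure_sd=0.0,
        noise_sd=0.0, powerline_amp=0.0, wander_amp=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def clean_record(clean_config):
    return simulate_record(clean_config)


@pytest.fixture(scope="session")
def noisy_record():
    """Default-noise paired record with HR coupling — the realistic fixture."""
    return simulate_record(SyntheticConfig(duration_s=30.0, seed=3))


@pytest.fixture(scope="session")
def labeled_frames(noisy_record):
    rec, _ = noisy_record
    frames = preprocess_record(rec)
    labels = label_frames(frames, rec.fs)
    return frames, labels, rec.fs
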