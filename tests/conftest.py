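import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rpecg.signal_io import EcgRecord
from rpecg.synthetic_ecg import SynthConfig, generate_record


@pytest.fixture
def normal_record():
    """Clean 10 s sinus-rhythm record at 60 bpm, 250 Hz."""
    return generate_record(SynthConfig(
        class_label="normal", duration_s=10, fs=250, mean_hr_bpm=60,
        noise_sd=0.0, seed=7,
    ))


@pytest.fixture
def annotated_record():
    """Hand-built record with beats, rhythm changes and an artifact span."""
    fs = 250
    n = 10 * fs
    rng = np.random.default_rng(0)
    sig = 0.1 * rng.standard_normal(n)
    return EcgRecord(
        record_id="fixture01",
        signal=sig,
        fs=fs,
        beat_annotations=[(i * fs, "N") for i in range(1, 10)],
        rhythm_annotations=[(0, "(N"), (4 * fs, "(VF"), (8 * fs, "(N")],
        artifact_annotations=[(2 * fs, 3 * fs)],
    )


@pytest.fixture
def tiny_images():
    """Two-class separable 24x24 image set: bright vs dark quadrants."""
    rng = np.random.default_rng(3)
    X, y = [], []
    for i in range(40):
        img = rng.uniform(0, 0.2, size=(24, 24, 3)).astype(np.float32)
        if i % 2:
            img[:12, :12] += 0.7
            y.append("bright")
        else:
            img[12:, 12:] += 0.7
            y.append("dark")
        X.append(np.clip(img, 0, 1))
    return np.stack(X), np.array(y)
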