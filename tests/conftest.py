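import numpy as np
import pytest

from ecgid import (
    ECGRecording,
    PopulationConfig,
    PreprocessConfig,
    Segment,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sine_recording():
    """10 s of a 10 Hz tone at fs=128 (passband of the default filter)."""
    fs = 128.0
    t = np.arange(int(10 * fs)) / fs
    return ECGRecording(np.sin(2 * np.pi * 10.0 * t), fs, subject_id="sine")


@pytest.fixture
def default_population():
    return PopulationConfig(n_subjects=10, seed=7)


@pytest.fixture
def default_config():
    return PreprocessConfig()


def make_segment(samples, fs=128.0, subject="S00", activity="resting", index=0):
    return Segment(np.asarray(samples, dtype=float), fs, subject, activity, index)
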