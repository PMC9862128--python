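"""Raw ECG cleaning and windowing.

The pipeline is: DC removal (mean subtraction) -> zero-phase band-pass
filtering (default 0.67-45 Hz, removing baseline wander below ~0.7 Hz and
50/60 Hz powerline interference) -> splitting into fixed-length windows of
``W`` seconds (default 5 s, long enough for several heartbeats).  No beat
detection or artifact rejection is performed anywhere: the method is
deliberately non-fiducial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError
from .records import ECGRecording, Segment

__all__ = [
    "PreprocessConfig",
    "remove_dc",
    "design_bandpass",
    "bandpass_filter",
    "segment_recording",
    "preprocess_pipeline",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Cleaning and windowing parameters.

    highpass_cutoff / lowpass_cutoff : Hz
        Band edges; must satisfy 0 < high-pass < low-pass < Nyquist at use.
    filter_order : int
        Butterworth order (applied forward-backward, so the effective
        magnitude response is squared).
    window_seconds : float
        Window length W in seconds.
    overlap : float
        Fractional window overlap in [0, 1); default 0 (non-overlapping).
    """

    highpass_cutoff: float = 0.67
    lowpass_cutoff: float = 45.0
    filter_order: int = 4
    window_seconds: float = 5.0
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.highpass_cutoff <= 0 or self.lowpass_cutoff <= self.highpass_cutoff:
            raise ConfigurationError(
                "cutoffs must satisfy 0 < highpass_cutoff < lowpass_cutoff "
                f"(got {self.highpass_cutoff}, {self.lowpass_cutoff})"
            )
        if self.filter_order < 1:
            raise ConfigurationError("filter_order must be a positive integer")
        if self.window_seconds <= 0:
            raise ConfigurationError("window_seconds must be positive")
        if not 0.0 <= self.overlap < 1.0:
            raise ConfigurationError("overlap must lie in [0, 1)")


def remove_dc(recording: ECGRecording) -> ECGRecording:
    """Subtract the mean value (DC component) from the recording."""
    return recording.replace_samples(recording.samples - recording.samples.mean())


def design_bandpass(config: PreprocessConfig, sampling_rate: float):
    """Second-order-sections Butterworth band-pass for the given rate.

    Raises ConfigurationError when the upper cutoff reaches Nyquist.
    """
    nyquist = sampling_rate / 2.0
    if config.lowpass_cutoff >= nyquist:
        raise ConfigurationError(
            f"lowpass_cutoff {config.lowpass_cutoff} Hz must be below "
            f"Nyquist {nyquist} Hz at sampling rate {sampling_rate} Hz"
        )
    return sps.butter(
        config.filter_order,
        [config.highpass_cutoff, config.lowpass_cutoff],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )


def bandpass_filter(recording: ECGRecording, config: PreprocessConfig | None = None) -> ECGRecording:
    """Zero-phase band-pass filter (forward-backward Butterworth).

    Forward-backward application avoids phase distortion of the PQRST
    morphology; the price is that the magnitude response applies twice.
    """
    if config is None:
        config = PreprocessConfig()
    sos = design_bandpass(config, recording.sampling_rate)
    filtered = sps.sosfiltfilt(sos, recording.samples)
    return recording.replace_samples(filtered)


def segment_recording(
    recording: ECGRecording,
    window_seconds: float = 5.0,
    overlap: float = 0.0,
) -> list[Segment]:
    """Split a recording into fixed-length windows of ``window_seconds``.

    Windows are consecutive with the given fractional overlap (default
    non-overlapping); a trailing remainder shorter than one window is
    discarded.  A recording shorter than one window yields an empty list
    with a warning rather than an error.
    """
    if window_seconds <= 0:
        raise ConfigurationError("window_seconds must be positive")
    if not 0.0 <= overlap < 1.0:
        raise ConfigurationError("overlap must lie in [0, 1)")
    fs = recording.sampling_rate
    win = int(round(window_seconds * fs))
    if win < 1:
        raise ConfigurationError("window shorter than one sample")
    n = recording.samples.size
    if n < win:
        warnings.warn(
            f"recording of {n} samples is shorter than one {win}-sample window; "
            "returning no segments",
            stacklevel=2,
        )
        return []
    step = max(1, int(round(win * (1.0 - overlap))))
    starts = range(0, n - win + 1, step)
    return [
        Segment(
            samples=recording.samples[s : s + win],
            sampling_rate=fs,
            subject_id=recording.subject_id,
            activity=recording.activity,
            index=i,
        )
        for i, s in enumerate(starts)
    ]


def preprocess_pipeline(
    recording: ECGRecording, config: PreprocessConfig | None = None
) -> list[Segment]:
    """DC removal -> band-pass -> windowing, in that order."""
    if config is None:
        config = PreprocessConfig()
    cleaned = bandpass_filter(remove_dc(recording), config)
    return segment_recording(cleaned, config.window_seconds, config.overlap)
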