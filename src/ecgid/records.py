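"""Core domain containers: single-lead ECG recordings and fixed-length windows."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: recognised activity labels (the five acquisition conditions plus "unknown")
ACTIVITIES = ("resting", "math", "walking", "running", "handbike", "unknown")


@dataclass(frozen=True)
class ECGRecording:
    """A uniformly sampled single-lead voltage series.

    Amplitudes are arbitrary linear units (no millivolt calibration is
    enforced; downstream GAF rescaling is scale-invariant anyway).
    """

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = "unknown"
    activity: str = "unknown"
    lead: str = "II-modified"

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if not np.isfinite(self.sampling_rate) or self.sampling_rate <= 0:
            raise ValidationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("samples contain non-finite values (NaN/Inf)")
        if self.activity not in ACTIVITIES:
            raise ValidationError(
                f"activity must be one of {ACTIVITIES}, got {self.activity!r}"
            )

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.sampling_rate

    def replace_samples(self, samples: np.ndarray) -> "ECGRecording":
        """Copy of this recording with new samples (labels and rate preserved)."""
        return ECGRecording(
            samples=samples,
            sampling_rate=self.sampling_rate,
            subject_id=self.subject_id,
            activity=self.activity,
            lead=self.lead,
        )


@dataclass(frozen=True)
class Segment:
    """One fixed-length window cut from a recording."""

    samples: np.ndarray
    sampling_rate: float
    subject_id: str = "unknown"
    activity: str = "unknown"
    index: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValidationError("segment samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("segment samples contain non-finite values")
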