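"""Synthetic multi-subject, multi-activity ECG cohorts.

Each synthetic identity is a parameter vector of PQRST morphology: per-wave
Gaussian bumps on a beat phase axis, the standard sum-of-Gaussians ECG
formulation.  One beat spans one RR interval linearly in phase
``theta in [-pi, pi)`` and contributes

    z(theta) = sum_k a_k * exp(-(theta - theta_k)^2 / (2 b_k^2)),   k in {P,Q,R,S,T}.

Identity lives in the between-subject spread of (theta_k, a_k, b_k); nuisance
structure is heart-rate variability (per-beat RR jitter), per-beat morphology
jitter, activity-dependent heart rate and noise scaling, sinusoidal baseline
wander (< 0.7 Hz), 50 Hz powerline interference, and white sensor noise.

Everything is deterministic given the population seed; per-subject streams
are derived with ``SeedSequence(seed, spawn_key=(subject, ...))`` so a
subject's data never depends on generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .records import ECGRecording

__all__ = [
    "WAVE_NAMES",
    "SubjectParams",
    "ActivityProfile",
    "ACTIVITY_PROFILES",
    "NoiseModel",
    "WithinSubjectJitter",
    "PopulationConfig",
    "sample_subject",
    "generate_recording",
    "generate_cohort",
]

WAVE_NAMES = ("P", "Q", "R", "S", "T")

# canonical PQRST shape (dynamical-ECG-model defaults, amplitude-scaled)
_THETA = np.array([-1.22, -0.26, 0.0, 0.26, 1.75])
_AMP = np.array([0.12, -0.5, 1.5, -0.75, 0.35])
_WIDTH = np.array([0.25, 0.10, 0.10, 0.10, 0.40])

_HR_LO, _HR_HI = 30.0, 220.0  # physical heart-rate envelope (bpm)
_POP_HR_LO, _POP_HR_HI = 50.0, 100.0  # resting population range (bpm)


@dataclass(frozen=True)
class SubjectParams:
    """One synthetic identity: PQRST morphology plus rhythm parameters."""

    wave_angles: np.ndarray  # radians, ordered P<Q<R<S<T, in (-pi, pi)
    wave_amplitudes: np.ndarray  # arbitrary linear units
    wave_widths: np.ndarray  # radians, > 0
    mean_hr: float  # beats/minute
    hr_sd: float  # beat-to-beat HR standard deviation (bpm)
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        for name in ("wave_angles", "wave_amplitudes", "wave_widths"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        th = self.wave_angles
        if th.shape != (5,) or np.any(np.diff(th) <= 0):
            raise ConfigurationError("wave angles must be 5 strictly increasing values")
        if th.min() <= -np.pi or th.max() >= np.pi:
            raise ConfigurationError("wave angles must lie in (-pi, pi)")
        if np.any(self.wave_widths <= 0):
            raise ConfigurationError("wave widths must be positive")
        if not _HR_LO <= self.mean_hr <= _HR_HI:
            raise ConfigurationError(f"mean_hr {self.mean_hr} outside [{_HR_LO}, {_HR_HI}] bpm")
        if self.hr_sd < 0:
            raise ConfigurationError("hr_sd must be non-negative")


@dataclass(frozen=True)
class ActivityProfile:
    """Multipliers applied to a subject's rhythm and noise during an activity."""

    name: str
    hr_scale: float = 1.0
    motion_noise_scale: float = 1.0
    baseline_wander_scale: float = 1.0

    def __post_init__(self) -> None:
        if min(self.hr_scale, self.motion_noise_scale, self.baseline_wander_scale) <= 0:
            raise ConfigurationError("activity scales must be positive")


#: monotone HR/noise escalation across the five acquisition conditions
ACTIVITY_PROFILES: dict[str, ActivityProfile] = {
    "resting": ActivityProfile("resting", 1.0, 1.0, 1.0),
    "math": ActivityProfile("math", 1.15, 1.2, 1.0),
    "walking": ActivityProfile("walking", 1.5, 2.0, 1.5),
    "running": ActivityProfile("running", 2.0, 3.5, 2.0),
    "handbike": ActivityProfile("handbike", 1.6, 3.0, 1.8),
}


@dataclass(frozen=True)
class NoiseModel:
    """Additive nuisance components, in the recording's amplitude units."""

    wander_freq: float = 0.3  # Hz, respiratory-band baseline wander
    wander_amp: float = 0.2
    powerline_freq: float = 50.0  # Hz mains
    powerline_amp: float = 0.05
    white_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.wander_freq <= 0 or self.powerline_freq <= 0:
            raise ConfigurationError("noise frequencies must be positive")
        if min(self.wander_amp, self.powerline_amp, self.white_sd) < 0:
            raise ConfigurationError("noise amplitudes must be non-negative")

    @classmethod
    def silent(cls) -> "NoiseModel":
        return cls(wander_amp=0.0, powerline_amp=0.0, white_sd=0.0)


@dataclass(frozen=True)
class WithinSubjectJitter:
    """Per-beat morphology jitter standard deviations (same shapes as the means)."""

    theta_sd: np.ndarray = field(default_factory=lambda: 0.03 * np.abs(_THETA))
    amp_sd: np.ndarray = field(default_factory=lambda: 0.03 * np.abs(_AMP))
    width_sd: np.ndarray = field(default_factory=lambda: 0.03 * np.abs(_WIDTH))

    def __post_init__(self) -> None:
        for name in ("theta_sd", "amp_sd", "width_sd"):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (5,) or np.any(arr < 0):
                raise ConfigurationError(f"{name} must be 5 non-negative values")
            object.__setattr__(self, name, arr)

    @classmethod
    def none(cls) -> "WithinSubjectJitter":
        z = np.zeros(5)
        return cls(z, z, z)


@dataclass(frozen=True)
class PopulationConfig:
    """Population distribution of subject parameters plus acquisition settings.

    Between-subject standard deviations default to 15% of each morphology
    mean and within-subject per-beat jitter to 3%, so between-subject spread
    dominates within-subject variation (the identifiability condition, which
    is enforced: a population whose jitter reaches its between-subject spread
    carries no identity signal).
    """

    n_subjects: int = 10
    theta_mean: np.ndarray = field(default_factory=lambda: _THETA.copy())
    theta_between_sd: np.ndarray = field(default_factory=lambda: 0.15 * np.abs(_THETA))
    amp_mean: np.ndarray = field(default_factory=lambda: _AMP.copy())
    amp_between_sd: np.ndarray = field(default_factory=lambda: 0.15 * np.abs(_AMP))
    width_mean: np.ndarray = field(default_factory=lambda: _WIDTH.copy())
    width_between_sd: np.ndarray = field(default_factory=lambda: 0.15 * np.abs(_WIDTH))
    hr_mean: float = 65.0
    hr_between_sd: float = 9.75
    hrv_mean: float = 3.0  # within-subject beat-to-beat HR sd (bpm)
    hrv_between_sd: float = 1.0
    jitter: WithinSubjectJitter = field(default_factory=WithinSubjectJitter)
    noise: NoiseModel = field(default_factory=NoiseModel)
    sampling_rate: float = 128.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.sampling_rate < 100.0:
            raise ConfigurationError("sampling_rate must be >= 100 Hz")
        for name in (
            "theta_mean",
            "theta_between_sd",
            "amp_mean",
            "amp_between_sd",
            "width_mean",
            "width_between_sd",
        ):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        pairs = [
            ("theta", self.theta_between_sd, self.jitter.theta_sd),
            ("amp", self.amp_between_sd, self.jitter.amp_sd),
            ("width", self.width_between_sd, self.jitter.width_sd),
        ]
        for name, between, within in pairs:
            ok = (between > within) | ((between == 0) & (within == 0))
            if not np.all(ok):
                raise ConfigurationError(
                    f"{name}: between-subject sd must exceed within-subject jitter "
                    "sd for every wave (identifiability condition)"
                )


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, max_tries: int = 1000):
    """Rejection-sampled truncated normal (scalar or vector)."""
    for _ in range(max_tries):
        draw = rng.normal(mean, sd)
        if np.all((draw >= lo) & (draw <= hi)):
            return draw
    return np.clip(rng.normal(mean, sd), lo, hi)


def sample_subject(
    population: PopulationConfig,
    rng: np.random.Generator,
    subject_id: str = "subject",
) -> SubjectParams:
    """Draw one identity from the population (deterministic given the rng state)."""
    for _ in range(1000):
        theta = rng.normal(population.theta_mean, population.theta_between_sd)
        if np.all(np.diff(theta) > 0) and theta.min() > -np.pi and theta.max() < np.pi:
            break
    else:
        raise ConfigurationError("could not draw ordered wave angles; sds too wide")
    amp = rng.normal(population.amp_mean, population.amp_between_sd)
    width = np.maximum(
        rng.normal(population.width_mean, population.width_between_sd), 1e-3
    )
    mean_hr = float(
        _truncated_normal(
            rng, population.hr_mean, population.hr_between_sd, _POP_HR_LO, _POP_HR_HI
        )
    )
    hr_sd = float(max(0.0, rng.normal(population.hrv_mean, population.hrv_between_sd)))
    return SubjectParams(theta, amp, width, mean_hr, hr_sd, subject_id)


def generate_recording(
    subject: SubjectParams,
    activity: ActivityProfile,
    duration: float,
    fs: float,
    rng: np.random.Generator,
    jitter: WithinSubjectJitter | None = None,
    noise: NoiseModel | None = None,
) -> ECGRecording:
    """Synthesise one labelled recording of ``round(duration * fs)`` samples."""
    if jitter is None:
        jitter = WithinSubjectJitter()
    if noise is None:
        noise = NoiseModel()
    if fs < 100.0:
        raise ConfigurationError("sampling rate must be >= 100 Hz")
    hr_target = subject.mean_hr * activity.hr_scale
    if not _HR_LO <= hr_target <= _HR_HI:
        raise ConfigurationError(
            f"activity-scaled heart rate {hr_target:.1f} bpm outside "
            f"[{_HR_LO}, {_HR_HI}]"
        )
    if duration < 60.0 / hr_target:
        raise ConfigurationError("duration must cover at least one beat")

    n = int(round(duration * fs))
    # enough beats to cover the recording even at the slow end of the HR draw
    n_beats = int(np.ceil(duration * _HR_HI / 60.0)) + 2
    beat_hr = np.clip(rng.normal(hr_target, subject.hr_sd, size=n_beats), _HR_LO, _HR_HI)
    rr = 60.0 / beat_hr
    onsets = np.concatenate(([0.0], np.cumsum(rr)))

    theta_b = subject.wave_angles + rng.normal(0.0, 1.0, (n_beats, 5)) * jitter.theta_sd
    amp_b = subject.wave_amplitudes + rng.normal(0.0, 1.0, (n_beats, 5)) * jitter.amp_sd
    width_b = np.maximum(
        subject.wave_widths + rng.normal(0.0, 1.0, (n_beats, 5)) * jitter.width_sd, 1e-3
    )

    t = np.arange(n, dtype=np.float64) / fs
    k = np.clip(np.searchsorted(onsets, t, side="right") - 1, 0, n_beats - 1)
    phase = -np.pi + 2.0 * np.pi * (t - onsets[k]) / rr[k]
    z = np.zeros(n)
    for w in range(5):
        z += amp_b[k, w] * np.exp(-((phase - theta_b[k, w]) ** 2) / (2.0 * width_b[k, w] ** 2))

    wander_phase = rng.uniform(0.0, 2.0 * np.pi)
    mains_phase = rng.uniform(0.0, 2.0 * np.pi)
    if noise.wander_amp > 0:
        z += (
            noise.wander_amp
            * activity.baseline_wander_scale
            * np.sin(2.0 * np.pi * noise.wander_freq * t + wander_phase)
        )
    if noise.powerline_amp > 0:
        z += noise.powerline_amp * np.sin(2.0 * np.pi * noise.powerline_freq * t + mains_phase)
    if noise.white_sd > 0:
        z += noise.white_sd * activity.motion_noise_scale * rng.standard_normal(n)

    return ECGRecording(
        samples=z,
        sampling_rate=fs,
        subject_id=subject.subject_id,
        activity=activity.name,
    )


def generate_cohort(
    population: PopulationConfig,
    activities: list[ActivityProfile] | list[str] | None = None,
    duration_per_activity: float = 120.0,
) -> list[ECGRecording]:
    """Generate ``n_subjects x len(activities)`` labelled recordings.

    Per-subject rng streams are spawned from the population seed keyed by
    subject index (and activity index), so the cohort is bit-reproducible
    and order-independent.
    """
    if activities is None:
        activities = [ACTIVITY_PROFILES["resting"]]
    profiles = [
        ACTIVITY_PROFILES[a] if isinstance(a, str) else a for a in activities
    ]
    recordings: list[ECGRecording] = []
    for i in range(population.n_subjects):
        rng_subject = np.random.default_rng(
            np.random.SeedSequence(population.seed, spawn_key=(i,))
        )
        subject = sample_subject(population, rng_subject, subject_id=f"S{i:02d}")
        for j, profile in enumerate(profiles):
            rng_rec = np.random.default_rng(
                np.random.SeedSequence(population.seed, spawn_key=(i, j + 1))
            )
            recordings.append(
                generate_recording(
                    subject,
                    profile,
                    duration_per_activity,
                    population.sampling_rate,
                    rng_rec,
                    jitter=population.jitter,
                    noise=population.noise,
                )
            )
    return recordings
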