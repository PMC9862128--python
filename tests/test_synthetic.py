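"""Synthetic cohort generator: determinism, rhythm, noise structure, identity."""

import numpy as np
import pytest
from scipy import signal as sps

from ecgid import (
    ACTIVITY_PROFILES,
    ConfigurationError,
    NoiseModel,
    PopulationConfig,
    PreprocessConfig,
    WithinSubjectJitter,
    bandpass_filter,
    generate_cohort,
    generate_recording,
    sample_subject,
)


def quiet_subject(population, seed=0, hr=60.0, hr_sd=0.0):
    rng = np.random.default_rng(seed)
    subject = sample_subject(population, rng, "S00")
    from dataclasses import replace

    return replace(subject, mean_hr=hr, hr_sd=hr_sd)


class TestSampleSubject:
    def test_deterministic_given_seed(self, default_population):
        a = sample_subject(default_population, np.random.default_rng(1))
        b = sample_subject(default_population, np.random.default_rng(1))
        np.testing.assert_array_equal(a.wave_amplitudes, b.wave_amplitudes)
        assert a.mean_hr == b.mean_hr

    def test_different_seeds_differ(self, default_population):
        a = sample_subject(default_population, np.random.default_rng(1))
        b = sample_subject(default_population, np.random.default_rng(2))
        assert not np.array_equal(a.wave_amplitudes, b.wave_amplitudes)

    def test_identifiability_guard(self):
        bad_jitter = WithinSubjectJitter(
            theta_sd=np.zeros(5),
            amp_sd=np.full(5, 10.0),  # dwarfs the 15% between-subject sd
            width_sd=np.zeros(5),
        )
        with pytest.raises(ConfigurationError):
            PopulationConfig(jitter=bad_jitter)

    def test_wave_order_invariant_holds(self, default_population):
        for seed in range(20):
            s = sample_subject(default_population, np.random.default_rng(seed))
            assert np.all(np.diff(s.wave_angles) > 0)
            assert 30 <= s.mean_hr <= 220


class TestGenerateRecording:
    def test_beat_count_in_expected_range(self, default_population):
        subject = quiet_subject(default_population, hr=75.0, hr_sd=2.0)
        rec = generate_recording(
            subject,
            ACTIVITY_PROFILES["resting"],
            10.0,
            128.0,
            np.random.default_rng(3),
        )
        assert rec.samples.size == 1280
        # count R peaks: dominant positive deflections
        height = 0.5 * rec.samples.max()
        peaks, _ = sps.find_peaks(rec.samples, height=height, distance=0.3 * 128)
        assert 8 <= peaks.size <= 17

    def test_noiseless_recording_is_periodic(self, default_population):
        subject = quiet_subject(default_population, hr=60.0, hr_sd=0.0)
        rec = generate_recording(
            subject,
            ACTIVITY_PROFILES["resting"],
            8.0,
            128.0,
            np.random.default_rng(0),
            jitter=WithinSubjectJitter.none(),
            noise=NoiseModel.silent(),
        )
        period = 128  # 60 bpm at fs=128
        x = rec.samples
        assert np.abs(x[period:] - x[:-period]).max() < 1e-9

    def test_same_seed_is_bit_identical(self, default_population):
        subject = quiet_subject(default_population)
        args = (subject, ACTIVITY_PROFILES["walking"], 10.0, 128.0)
        a = generate_recording(*args, np.random.default_rng(9))
        b = generate_recording(*args, np.random.default_rng(9))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_running_halves_resting_rr(self, default_population):
        subject = quiet_subject(default_population, hr=70.0, hr_sd=0.0)
        kwargs = dict(jitter=WithinSubjectJitter.none(), noise=NoiseModel.silent())
        mean_rr = {}
        for name in ("resting", "running"):
            rec = generate_recording(
                subject, ACTIVITY_PROFILES[name], 30.0, 128.0,
                np.random.default_rng(0), **kwargs,
            )
            peaks, _ = sps.find_peaks(
                rec.samples, height=0.5 * rec.samples.max(), distance=0.2 * 128
            )
            mean_rr[name] = np.diff(peaks).mean() / 128.0
        assert mean_rr["running"] == pytest.approx(0.5 * mean_rr["resting"], rel=0.01)

    def test_nonphysical_hr_rejected(self, default_population):
        subject = quiet_subject(default_population, hr=115.0)
        fast = ACTIVITY_PROFILES["running"]  # 2.0 x 115 = 230 bpm
        with pytest.raises(ConfigurationError):
            generate_recording(subject, fast, 10.0, 128.0, np.random.default_rng(0))


class TestNoiseStructure:
    def spectrum_peak(self, samples, fs, lo, hi):
        freqs, power = sps.periodogram(samples, fs=fs)
        band = (freqs >= lo) & (freqs <= hi)
        return freqs[band][np.argmax(power[band])]

    def test_wander_and_powerline_peaks(self, default_population):
        subject = quiet_subject(default_population)
        rec = generate_recording(
            subject,
            ACTIVITY_PROFILES["resting"],
            60.0,
            128.0,
            np.random.default_rng(5),
            noise=NoiseModel(wander_amp=0.3, powerline_amp=0.1, white_sd=0.0),
        )
        noise = default_population.noise
        assert abs(self.spectrum_peak(rec.samples, 128.0, 0.05, 0.6) - noise.wander_freq) <= 0.05
        assert abs(self.spectrum_peak(rec.samples, 128.0, 45.0, 55.0) - noise.powerline_freq) <= 0.5

    def test_bandpass_removes_most_nuisance_power(self, default_population):
        """The default cleaning strips >=90% of wander and powerline power."""
        subject = quiet_subject(default_population)
        rec = generate_recording(
            subject,
            ACTIVITY_PROFILES["resting"],
            60.0,
            128.0,
            np.random.default_rng(5),
        )
        out = bandpass_filter(rec, PreprocessConfig())

        def band_power(x, lo, hi):
            freqs, power = sps.periodogram(x, fs=128.0)
            sel = (freqs >= lo) & (freqs <= hi)
            return power[sel].sum()

        noise = default_population.noise
        for lo, hi in [
            (noise.wander_freq - 0.1, noise.wander_freq + 0.1),
            (noise.powerline_freq - 0.5, noise.powerline_freq + 0.5),
        ]:
            assert band_power(out.samples, lo, hi) <= 0.1 * band_power(rec.samples, lo, hi)


class TestCohort:
    def test_cardinality_and_labels(self):
        pop = PopulationConfig(n_subjects=5, seed=3)
        recs = generate_cohort(pop, ["resting", "walking"], duration_per_activity=10.0)
        assert len(recs) == 10
        assert len({r.subject_id for r in recs}) == 5
        assert {r.activity for r in recs} == {"resting", "walking"}

    def test_same_seed_bit_identical(self):
        pop = PopulationConfig(n_subjects=3, seed=11)
        a = generate_cohort(pop, ["resting"], 10.0)
        b = generate_cohort(pop, ["resting"], 10.0)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.samples, rb.samples)

    def test_between_subject_spread_exceeds_jitter(self):
        """Mean |a_R difference| between subjects > 3x the per-beat jitter sd."""
        pop = PopulationConfig(n_subjects=50, seed=21)
        amps = []
        for i in range(50):
            rng = np.random.default_rng(np.random.SeedSequence(pop.seed, spawn_key=(i,)))
            amps.append(sample_subject(pop, rng).wave_amplitudes[2])
        amps = np.asarray(amps)
        diffs = np.abs(amps[:, None] - amps[None, :])
        mean_diff = diffs[np.triu_indices(50, 1)].mean()
        assert mean_diff > 3.0 * pop.jitter.amp_sd[2]
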