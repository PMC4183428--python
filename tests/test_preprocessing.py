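"""Signal preprocessing: filters, envelopes, spectrograms, trial scoring."""

import numpy as np
import pytest

from wakeprob.preprocessing import (
    BreathTrial,
    InvalidConfigurationError,
    RawSignal,
    SpectrogramMatrix,
    band_powers,
    filter_emg,
    median_channel_spectrogram,
    multitaper_spectrogram,
    score_trials,
    scoring_window,
    squeeze_amplitude,
)

FS = 200.0


def _sine(freq, duration=10.0, fs=FS, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return RawSignal(amp * np.sin(2 * np.pi * freq * t), fs, label=f"{freq}Hz")


class TestFilterEMG:
    def test_mains_notch_attenuates_60hz_tone(self):
        out = filter_emg(_sine(60.0))
        # steady-state region away from filtfilt edge transients
        mid = slice(int(FS), -int(FS))
        ratio = np.sqrt(np.mean(out.samples[mid] ** 2)) / np.sqrt(0.5)
        assert ratio < 0.01

    def test_passband_tone_survives(self):
        out = filter_emg(_sine(30.0))
        mid = slice(int(FS), -int(FS))
        assert np.sqrt(np.mean(out.samples[mid] ** 2)) > 0.9 * np.sqrt(0.5)

    def test_zero_in_zero_out(self):
        out = filter_emg(RawSignal(np.zeros(1000), FS))
        assert np.allclose(out.samples, 0.0)

    def test_linearity(self, rng):
        x = RawSignal(rng.normal(size=2000), FS)
        y = RawSignal(rng.normal(size=2000), FS)
        combo = RawSignal(2.0 * x.samples - 3.0 * y.samples, FS)
        lhs = filter_emg(combo).samples
        rhs = 2.0 * filter_emg(x).samples - 3.0 * filter_emg(y).samples
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_fs_too_low_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            filter_emg(RawSignal(np.zeros(100), fs=100.0), low=10, high=70)


class TestSqueezeAmplitude:
    def test_unit_sinusoid_envelope_near_one(self):
        sig = filter_emg(_sine(30.0, duration=20.0))
        obs = squeeze_amplitude(sig, trial_time=10.0, window=1.0)
        assert obs.present
        assert abs(obs.log_amplitude) < 0.05  # log of ~unit envelope

    def test_window_beyond_recording_is_missing_not_error(self):
        sig = _sine(30.0, duration=5.0)
        obs = squeeze_amplitude(sig, trial_time=0.2, window=1.0)
        assert not obs.present
        assert np.isnan(obs.log_amplitude)

    def test_amplitude_scales_log(self):
        a = squeeze_amplitude(_sine(30.0, amp=2.0), 5.0)
        b = squeeze_amplitude(_sine(30.0, amp=1.0), 5.0)
        assert a.log_amplitude - b.log_amplitude == pytest.approx(np.log(2.0),
                                                                  abs=0.02)


class TestMultitaperSpectrogram:
    def test_default_grid_step(self):
        spec = multitaper_spectrogram(_sine(10.0, duration=20.0))
        steps = np.diff(spec.times)
        assert np.allclose(steps, 0.25)

    def test_parseval_white_noise(self, rng):
        # integrated PSD per window should match the signal variance
        sigma = 1.7
        sig = RawSignal(rng.normal(0, sigma, int(60 * FS)), FS)
        spec = multitaper_spectrogram(sig)
        total = spec.power.sum(axis=1) * spec.df
        assert abs(np.mean(total) - sigma**2) / sigma**2 < 0.1

    def test_zero_signal_zero_power(self):
        spec = multitaper_spectrogram(RawSignal(np.zeros(int(10 * FS)), FS))
        assert np.allclose(spec.power, 0.0)

    def test_short_signal_single_window(self):
        spec = multitaper_spectrogram(RawSignal(np.ones(int(2 * FS)), FS),
                                      win=6.0)
        assert spec.times.size == 1


class TestMedianChannelSpectrogram:
    def _spec(self, power):
        n_t, n_f = power.shape
        return SpectrogramMatrix(np.arange(n_t, dtype=float),
                                 np.arange(n_f, dtype=float), power)

    def test_single_channel_identity(self, rng):
        s = self._spec(rng.uniform(size=(4, 6)))
        out = median_channel_spectrogram([s])
        assert np.array_equal(out.power, s.power)

    def test_outlier_channel_is_ignored(self, rng):
        base = rng.uniform(1.0, 2.0, size=(5, 8))
        specs = [self._spec(base.copy()) for _ in range(8)]
        specs[3].power[2, 4] *= 10.0
        out = median_channel_spectrogram(specs)
        # sorted-middle oracle over the channel axis
        stacked = np.stack([s.power for s in specs])
        oracle = np.sort(stacked, axis=0)
        expected = 0.5 * (oracle[3] + oracle[4])
        assert np.allclose(out.power, expected)
        assert out.power[2, 4] == pytest.approx(base[2, 4])

    def test_identical_channels(self, rng):
        s = self._spec(rng.uniform(size=(3, 5)))
        out = median_channel_spectrogram([s, s, s])
        assert np.allclose(out.power, s.power)

    def test_mismatched_grids_rejected(self, rng):
        a = self._spec(rng.uniform(size=(3, 5)))
        b = SpectrogramMatrix(np.arange(3) + 0.5, np.arange(5.0),
                              rng.uniform(size=(3, 5)))
        with pytest.raises(ValueError, match="grid"):
            median_channel_spectrogram([a, b])


class TestBandPowers:
    def test_pure_alpha_tone_lands_in_alpha(self):
        spec = multitaper_spectrogram(_sine(10.0, duration=30.0))
        bp = band_powers(spec)
        total = spec.power.sum(axis=1) * spec.df
        assert np.all(bp.alpha[5:-5] / total[5:-5] > 0.95)

    def test_bands_partition_total(self, rng):
        spec = multitaper_spectrogram(
            RawSignal(rng.normal(size=int(30 * FS)), FS))
        bp = band_powers(spec)
        mask = (spec.freqs >= 0.5) & (spec.freqs < 12.0)
        total = spec.power[:, mask].sum(axis=1) * spec.df
        assert np.allclose(bp.delta + bp.theta + bp.alpha, total, rtol=1e-12)

    def test_zero_spectrogram(self):
        spec = SpectrogramMatrix(np.arange(3.0), np.linspace(0, 20, 50),
                                 np.zeros((3, 50)))
        bp = band_powers(spec)
        assert np.all(bp.delta == 0) and np.all(bp.alpha == 0)

    def test_empty_band_rejected(self):
        spec = SpectrogramMatrix(np.arange(3.0), np.array([0.0, 10.0, 20.0]),
                                 np.ones((3, 3)))
        with pytest.raises(InvalidConfigurationError):
            band_powers(spec, {"delta": (0.5, 5.0), "theta": (5.0, 8.0),
                               "alpha": (8.0, 9.0)})


class TestScoreTrials:
    def test_overlapping_squeeze_is_correct(self):
        out = score_trials([10.0], [(9.5, 10.5)])
        assert out[0].response == "correct"

    def test_no_squeeze_is_incorrect(self):
        out = score_trials([10.0], [(30.0, 31.0)])
        assert out[0].response == "incorrect"

    def test_artifact_overrides(self):
        out = score_trials([10.0], [(9.5, 10.5)], [(9.0, 11.0)])
        assert out[0].response == "missing"

    def test_one_trial_per_inhale(self, rng):
        inhales = np.cumsum(rng.uniform(3, 5, 30))
        squeezes = [(t - 0.3, t + 0.3) for t in inhales[::2]]
        out = score_trials(inhales, squeezes)
        assert len(out) == 30
        assert [t.time for t in out] == sorted(t.time for t in out)

    def test_misaligned_squeeze_is_incorrect(self):
        # squeeze outside every apex's alignment window
        out = score_trials([10.0, 14.0, 18.0], [(11.9, 12.1)],
                           half_breath=0.5)
        assert [t.response for t in out] == ["incorrect"] * 3


class TestScoringWindow:
    def _trials(self, pattern, spacing=4.0):
        return [BreathTrial(i * spacing, r) for i, r in enumerate(pattern)]

    def test_starts_at_first_run_of_three_correct(self):
        trials = self._trials(
            ["incorrect", "correct", "correct", "correct", "incorrect"])
        out = scoring_window(trials)
        assert out[0].time == trials[1].time

    def test_stops_ten_minutes_after_last_correct(self):
        trials = [BreathTrial(t, "correct") for t in (0.0, 300.0, 600.0)]
        trials += [BreathTrial(t, "incorrect") for t in (900.0, 1200.0, 1201.0)]
        out = scoring_window(trials)
        assert out[-1].time == 1200.0

    def test_all_incorrect_empty_with_warning(self):
        with pytest.warns(UserWarning):
            out = scoring_window(self._trials(["incorrect"] * 5))
        assert out == []

    def test_never_reorders_or_relabels(self):
        trials = self._trials(["correct"] * 3 + ["incorrect", "correct"])
        out = scoring_window(trials)
        assert all(a.time == b.time and a.response == b.response
                   for a, b in zip(out, trials))
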