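"""Wavelet spectrogram correctness: localization, normalization, alignment."""

import numpy as np
import pytest

from attnephys.signals import ContinuousSignal
from attnephys.spectral import (
    BandDefinition,
    align_power,
    band_power,
    default_freq_grid,
    morlet_cwt,
    peak_normalize_log10,
    stim_band_response,
)


def tone(freq, fs=1000.0, duration=20.0, amp=1.0):
    t = np.arange(0, duration, 1 / fs)
    return ContinuousSignal(amp * np.sin(2 * np.pi * freq * t), fs=fs)


class TestMorletCwt:
    def test_pure_tone_peaks_at_nearest_grid_frequency(self):
        spec = morlet_cwt(tone(10.0))
        avg = spec.power.mean(axis=1)
        peak = spec.freqs_hz[np.argmax(avg)]
        grid_step = spec.freqs_hz[np.argmax(avg) + 1] - peak
        assert abs(peak - 10.0) <= grid_step

    def test_zero_signal_gives_zero_power(self):
        sig = ContinuousSignal(np.zeros(5000) + 0.0, fs=1000.0)
        spec = morlet_cwt(sig)
        assert np.abs(spec.power).max() < 1e-20

    def test_two_tones_give_two_local_maxima(self):
        t = np.arange(0, 20, 1 / 1000)
        sig = ContinuousSignal(
            np.sin(2 * np.pi * 8 * t) + np.sin(2 * np.pi * 40 * t), fs=1000.0
        )
        avg = morlet_cwt(sig).power.mean(axis=1)
        freqs = morlet_cwt(sig).freqs_hz
        local_max = [
            freqs[i]
            for i in range(1, len(avg) - 1)
            if avg[i] > avg[i - 1] and avg[i] > avg[i + 1] and avg[i] > 0.1 * avg.max()
        ]
        assert len(local_max) == 2
        assert min(abs(f - 8) for f in local_max) < 1.0
        assert min(abs(f - 40) for f in local_max) < 4.0

    def test_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_cwt(tone(10.0, fs=100.0), freqs_hz=np.array([60.0]))

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="3 cycles"):
            morlet_cwt(tone(10.0, duration=1.0), freqs_hz=np.array([1.0, 10.0]))

    def test_time_averaged_tone_power_invariant_to_duration(self):
        # Parseval-style: once >= 10 cycles are present the time-averaged
        # power of a unit tone does not depend on record length
        grid = default_freq_grid()
        p20 = morlet_cwt(tone(10.0, duration=20.0), grid).power.mean(axis=1).max()
        p60 = morlet_cwt(tone(10.0, duration=60.0), grid).power.mean(axis=1).max()
        assert p60 == pytest.approx(p20, rel=0.02)


class TestBandPower:
    def test_tone_band_dominates_remote_band(self):
        spec = morlet_cwt(tone(8.0))
        theta = band_power(spec, BandDefinition("t", 7, 10)).samples.mean()
        gamma = band_power(spec, BandDefinition("g", 30, 50)).samples.mean()
        assert theta / gamma > 10

    def test_peak_log10_global_max_is_exactly_zero(self):
        sig, _ = _noisy_tone()
        spec = morlet_cwt(sig)
        norm = peak_normalize_log10(spec)
        assert norm.power.max() == 0.0
        trace = band_power(spec, BandDefinition("t", 7, 10), normalize="peak_log10")
        assert trace.samples.max() <= 0.0

    def test_white_noise_band_means_are_comparable(self, rng):
        sig = ContinuousSignal(rng.standard_normal(60000), fs=1000.0)
        spec = morlet_cwt(sig)
        # adjacent bands of a flat spectrum should agree within sampling error
        b1 = band_power(spec, BandDefinition("a", 20, 30)).samples.mean()
        b2 = band_power(spec, BandDefinition("b", 30, 40)).samples.mean()
        assert b1 / b2 == pytest.approx(1.0, rel=0.5)

    def test_empty_band_rejected(self):
        spec = morlet_cwt(tone(10.0), freqs_hz=np.array([5.0, 10.0, 20.0]))
        with pytest.raises(ValueError, match="no grid"):
            band_power(spec, BandDefinition("x", 11.0, 12.0))


def _noisy_tone(seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(0, 20, 1 / 1000)
    x = np.sin(2 * np.pi * 8 * t) + 0.1 * rng.standard_normal(t.size)
    return ContinuousSignal(x, fs=1000.0), t


class TestAlignPower:
    def test_constant_trace_aligns_to_constant_zero_variance(self):
        power = ContinuousSignal(np.full(1000, 3.5), fs=100.0)
        al = align_power(power, np.array([3.0, 5.0, 7.0]), window=(1.0, 1.0))
        stats = al.group_stats()
        mean, var, n = stats[None]
        assert np.allclose(mean, 3.5) and np.allclose(var, 0.0) and n == 3

    def test_single_trial_has_zero_variance(self, rng):
        power = ContinuousSignal(rng.random(1000), fs=100.0)
        al = align_power(power, np.array([5.0]), window=(1.0, 1.0))
        _, var, n = al.group_stats()[None]
        assert n == 1 and np.allclose(var, 0.0)

    def test_power_step_at_event_appears_at_time_zero(self):
        fs = 100.0
        x = np.ones(2000)
        x[1000:] = 2.0  # step at t = 10 s
        power = ContinuousSignal(x, fs=fs)
        al = align_power(power, np.array([10.0]), window=(1.0, 1.0))
        mean, _, _ = al.group_stats()[None]
        i0 = np.searchsorted(al.time_s, 0.0)
        assert mean[i0 - 2] == 1.0 and mean[i0 + 1] == 2.0

    def test_edge_event_dropped_with_warning(self):
        power = ContinuousSignal(np.ones(500), fs=100.0)
        with pytest.warns(UserWarning, match="dropped"):
            al = align_power(power, np.array([0.1, 2.5]), window=(1.0, 1.0))
        assert al.traces.shape[0] == 1 and al.dropped_events_s.size == 1

    def test_grouping_by_labels(self, rng):
        power = ContinuousSignal(rng.random(4000), fs=100.0)
        events = np.array([5.0, 10.0, 15.0, 20.0])
        labels = [("long", "correct"), ("long", "incorrect")] * 2
        stats = align_power(power, events, (1.0, 1.0), labels).group_stats()
        assert {lab: n for lab, (_, _, n) in stats.items()} == {
            ("long", "correct"): 2,
            ("long", "incorrect"): 2,
        }


class TestStimBandResponse:
    def test_injected_gamma_tone_raises_stim_over_baseline(self):
        fs = 1000.0
        t = np.arange(0, 60, 1 / fs)
        rng = np.random.default_rng(1)
        x = 0.1 * rng.standard_normal(t.size)
        onsets = np.array([10.0, 25.0, 40.0])
        for on in onsets:
            sel = (t >= on) & (t < on + 2.0)
            x[sel] += np.sin(2 * np.pi * 40 * t[sel])
        spec = morlet_cwt(ContinuousSignal(x, fs=fs))
        power = band_power(spec, BandDefinition("lg", 30, 50), normalize="peak_log10")
        pairs = stim_band_response(power, onsets, train_len_s=2.0)
        assert len(pairs) == 3
        assert all(stim > base for base, stim in pairs)

    def test_no_tone_paired_difference_near_zero(self, rng):
        power = ContinuousSignal(rng.standard_normal(60000) ** 2, fs=1000.0)
        onsets = np.arange(5.0, 55.0, 10.0)
        pairs = stim_band_response(power, onsets, train_len_s=2.0)
        diffs = [stim - base for base, stim in pairs]
        assert abs(np.mean(diffs)) < 0.1

    def test_five_trains_give_five_pairs(self, rng):
        power = ContinuousSignal(rng.random(120000), fs=1000.0)
        onsets = np.arange(10.0, 110.0 + 1, 30.0)  # 10, 40, 70, 100
        onsets = np.arange(5.0, 5.0 + 5 * 20, 20.0)
        assert len(stim_band_response(power, onsets, train_len_s=2.0)) == 5

    def test_overlapping_trains_rejected(self, rng):
        power = ContinuousSignal(rng.random(10000), fs=1000.0)
        with pytest.raises(ValueError, match="overlap"):
            stim_band_response(power, np.array([2.0, 3.0]), train_len_s=2.0)
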