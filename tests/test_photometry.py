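"""Photometry processing: de-interleaving, motion correction, dF/F, features."""

import numpy as np
import pytest

from attnephys.photometry import (
    compute_dff,
    deinterleave,
    isosbestic_fit,
    motion_correct,
    process_recording,
    segment_trials,
    trial_features,
)
from attnephys.signals import ContinuousSignal
from attnephys.synth import PsychometricParams, TransientGroundTruth, gen_photometry, gen_session

from conftest import make_session


class TestDeinterleave:
    def test_even_odd_split(self):
        raw = ContinuousSignal(np.array([1.0, 10.0, 2.0, 20.0, 3.0, 30.0]), fs=40.0)
        rec = deinterleave(raw, phase=0)
        assert np.array_equal(rec.sig470.samples, [1, 2, 3])
        assert np.array_equal(rec.ref405.samples, [10, 20, 30])
        assert rec.sig470.fs == 20.0
        assert rec.ref405.t0 == pytest.approx(1 / 40.0)

    def test_phase_swaps_channels(self):
        raw = ContinuousSignal(np.array([1.0, 10.0, 2.0, 20.0]), fs=40.0)
        a = deinterleave(raw, phase=0)
        b = deinterleave(raw, phase=1)
        assert np.array_equal(a.sig470.samples, b.ref405.samples)
        assert np.array_equal(a.ref405.samples, b.sig470.samples)

    def test_reinterleaving_reproduces_input(self):
        raw = ContinuousSignal(np.arange(12.0), fs=40.0)
        rec = deinterleave(raw, phase=0)
        rebuilt = np.empty(12)
        rebuilt[0::2] = rec.sig470.samples
        rebuilt[1::2] = rec.ref405.samples
        assert np.array_equal(rebuilt, raw.samples)

    def test_odd_length_drops_last_with_warning(self):
        raw = ContinuousSignal(np.arange(7.0), fs=40.0)
        with pytest.warns(UserWarning, match="odd"):
            rec = deinterleave(raw)
        assert rec.sig470.samples.size == 3


class TestMotionCorrect:
    def test_exact_linear_relation_recovered(self, rng):
        ref = ContinuousSignal(rng.standard_normal(1000), fs=20.0)
        sig = ContinuousSignal(2.0 * ref.samples + 3.0, fs=20.0)
        a, b = isosbestic_fit(sig, ref)
        assert a == pytest.approx(2.0) and b == pytest.approx(3.0)
        out = motion_correct(sig, ref)
        assert np.allclose(out.samples, sig.samples.mean())

    def test_uncorrelated_reference_leaves_signal(self, rng):
        sig = ContinuousSignal(5.0 + rng.standard_normal(20000), fs=20.0)
        ref = ContinuousSignal(rng.standard_normal(20000), fs=20.0)
        a, _ = isosbestic_fit(sig, ref)
        assert abs(a) < 0.05
        out = motion_correct(sig, ref)
        assert np.corrcoef(out.samples, sig.samples)[0, 1] > 0.99

    def test_recovers_transients_under_motion(self):
        session = gen_session(20, psycho=PsychometricParams(p_omission=0.0), seed=2)
        truth_in = TransientGroundTruth(amplitudes=np.full(20, 0.05))
        rec, truth = gen_photometry(session, truth_in, motion_scale=0.5, noise_sd=0.0, seed=4)
        dff = process_recording(rec)
        assert np.corrcoef(dff.values, truth.transient_trace)[0, 1] > 0.99

    def test_constant_reference_rejected(self):
        sig = ContinuousSignal(np.arange(100.0), fs=20.0)
        ref = ContinuousSignal(np.full(100, 2.0), fs=20.0)
        with pytest.raises(ValueError, match="zero variance"):
            motion_correct(sig, ref)


class TestDff:
    def test_constant_trace_gives_zeros(self):
        out = compute_dff(ContinuousSignal(np.full(100, 7.0), fs=20.0))
        assert np.all(out.values == 0.0)

    def test_algebraic_identity_for_zero_median_modulation(self, rng):
        x = rng.standard_normal(1001)
        x -= np.median(x)  # median exactly 0
        f = 50.0 * (1 + 0.1 * x)
        out = compute_dff(ContinuousSignal(f, fs=20.0))
        assert np.allclose(out.values, 0.1 * x, atol=1e-12)

    def test_gain_invariance(self, rng):
        f = 100.0 + rng.random(500)
        d1 = compute_dff(ContinuousSignal(f, fs=20.0)).values
        d2 = compute_dff(ContinuousSignal(2.0 * f, fs=20.0)).values
        assert np.allclose(d1, d2)

    def test_non_positive_median_rejected(self):
        with pytest.raises(ValueError, match="median"):
            compute_dff(ContinuousSignal(np.full(100, -1.0), fs=20.0))


class TestSegmentation:
    def test_row_per_trial_with_matching_labels(self, small_session):
        rec, _ = gen_photometry(
            small_session, TransientGroundTruth(amplitudes=np.zeros(30)), seed=0
        )
        dff = process_recording(rec)
        aligned = segment_trials(dff, small_session)
        n_expected = len(small_session) - len(aligned.dropped_trials)
        assert aligned.traces.shape[0] == n_expected
        assert len(aligned.outcomes) == n_expected
        assert aligned.cue_lengths_s.size == n_expected

    def test_outcome_dependent_transients_separate_group_means(self):
        session = gen_session(
            40, psycho=PsychometricParams(p_correct=0.5, p_omission=0.0), seed=9
        )
        amps = np.array([0.08 if t.outcome == "correct" else 0.0 for t in session.trials])
        rec, _ = gen_photometry(
            session, TransientGroundTruth(amplitudes=amps), motion_scale=0.0,
            noise_sd=0.001, seed=1,
        )
        feats = trial_features(segment_trials(process_recording(rec), session))
        correct = feats[feats.outcome == "correct"].cue_mean.mean()
        incorrect = feats[feats.outcome == "incorrect"].cue_mean.mean()
        assert correct > incorrect + 0.01

    def test_constant_dff_gives_constant_rows(self):
        session = make_session(["L"] * 5, spacing=20.0)
        from attnephys.photometry import DffTrace

        dff = DffTrace(values=np.full(int(20.0 * 5 * 20 + 200), 0.25), fs=20.0)
        aligned = segment_trials(dff, session)
        assert np.all(aligned.traces == 0.25)

    def test_empty_session_rejected(self):
        from attnephys.photometry import DffTrace
        from attnephys.trials import SessionTable

        dff = DffTrace(values=np.zeros(100), fs=20.0)
        with pytest.raises(ValueError, match="empty"):
            segment_trials(dff, SessionTable(trials=[], session_duration_s=10.0))


class TestTrialFeatures:
    def _aligned_from_trace(self, trace, cue_len=2.0, fs=20.0):
        from attnephys.photometry import TrialAlignedTraces

        return TrialAlignedTraces(
            traces=np.asarray([trace]),
            time_s=(np.arange(len(trace)) - int(fs)) / fs,
            cue_lengths_s=np.array([cue_len]),
            outcomes=["correct"],
            fs=fs,
            pre_s=1.0,
            post_s=len(trace) / fs - 1.0,
        )

    def test_flat_trace_features(self):
        feats = trial_features(self._aligned_from_trace(np.full(120, 0.3)))
        row = feats.iloc[0]
        assert row.baseline_mean == pytest.approx(0.3)
        assert row.cue_mean == pytest.approx(0.3)
        assert row.peak_amplitude == pytest.approx(0.0)

    def test_boxcar_over_cue_window(self):
        fs = 20.0
        trace = np.zeros(120)
        trace[20:60] = 0.05  # exactly the 2 s cue window
        row = trial_features(self._aligned_from_trace(trace)).iloc[0]
        assert row.cue_mean == pytest.approx(0.05)
        assert row.peak_raw == pytest.approx(0.05)
        assert row.peak_amplitude == pytest.approx(0.05)

    def test_time_to_peak_within_one_sample(self):
        fs = 20.0
        trace = np.zeros(120)
        peak_idx = 20 + int(0.8 * fs)
        trace[peak_idx] = 1.0
        row = trial_features(self._aligned_from_trace(trace)).iloc[0]
        assert abs(row.time_to_peak_s - 0.8) <= 1 / fs

    def test_feature_vector_has_both_windows(self):
        feats = trial_features(self._aligned_from_trace(np.random.default_rng(0).random(120)))
        base_cols = [c for c in feats.columns if c.startswith("base_")]
        cue_cols = [
            c for c in feats.columns if c.startswith("cue_") and c != "cue_length_s"
        ]
        assert len(base_cols) == 11 and len(cue_cols) == 11

    def test_cue_longer_than_post_window_rejected(self):
        with pytest.raises(ValueError, match="cue window"):
            trial_features(self._aligned_from_trace(np.zeros(120), cue_len=9.0))
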