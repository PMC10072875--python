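"""Generator contracts: determinism, ground-truth fidelity, statistical oracles."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import stats as spstats

from attnephys import intracellular, photometry
from attnephys.synth import (
    PsychometricParams,
    TransientGroundTruth,
    gen_ecog,
    gen_ipsp_sweeps,
    gen_laminar,
    gen_noisy_current,
    gen_photometry,
    gen_session,
    gen_spike_sweeps,
)


class TestDeterminism:
    """Every generator is a pure function of (params, seed)."""

    def test_ecog_same_seed_bit_identical(self):
        a, ta = gen_ecog(30, swd_rate_per_min=1.0, seed=5)
        b, tb = gen_ecog(30, swd_rate_per_min=1.0, seed=5)
        assert np.array_equal(a.samples, b.samples)
        assert ta.events == tb.events

    def test_photometry_same_seed_identical(self, small_session):
        truth = TransientGroundTruth(amplitudes=np.full(30, 0.05))
        r1, _ = gen_photometry(small_session, truth, seed=3)
        r2, _ = gen_photometry(small_session, truth, seed=3)
        assert np.array_equal(r1.sig470.samples, r2.sig470.samples)
        assert np.array_equal(r1.ref405.samples, r2.ref405.samples)

    def test_current_same_seed_identical(self):
        a = gen_noisy_current(seed=9)
        b = gen_noisy_current(seed=9)
        assert np.array_equal(a.samples, b.samples)

    def test_session_same_seed_identical(self):
        a = gen_session(20, seed=4)
        b = gen_session(20, seed=4)
        assert a.trials == b.trials


class TestEcog:
    def test_rate_zero_gives_no_events_and_no_narrowband_peak(self):
        sig, truth = gen_ecog(120, swd_rate_per_min=0.0, seed=1)
        assert len(truth) == 0
        f, pxx = sps.welch(sig.samples, fs=sig.fs, nperseg=4096)
        inband = pxx[(f >= 7) & (f <= 10)].mean()
        neighbors = pxx[(f >= 4) & (f < 7)].mean()
        assert inband < 3 * neighbors  # smooth 1/f, no SWD line

    def test_event_count_within_poisson_99_interval(self):
        # 600 s at 0.5/min -> Poisson(5); 99% interval [0, 12]
        counts = [len(gen_ecog(600, swd_rate_per_min=0.5, seed=s)[1]) for s in range(5)]
        lo, hi = spstats.poisson.ppf([0.005, 0.995], 5)
        assert all(lo <= c <= hi for c in counts)

    def test_event_amplitude_and_bounds(self):
        sig, truth = gen_ecog(300, swd_rate_per_min=1.0, seed=2)
        assert len(truth) >= 1
        for (s, e, f0), amp in zip(truth.events, truth.amplitudes):
            assert 2.0 <= e - s <= 30.0
            assert 7.0 <= f0 <= 10.0
            assert amp > 0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_ecog(10, swd_rate_per_min=-1, seed=0)


class TestSession:
    def test_perfect_psychometrics_all_correct(self):
        sess = gen_session(
            30, psycho=PsychometricParams(p_correct=1.0, p_omission=0.0), seed=0
        )
        assert all(t.outcome == "correct" for t in sess.trials)

    def test_chance_accuracy_matches_binomial_oracle(self):
        psycho = PsychometricParams(p_correct=0.5, p_omission=0.0)
        outcomes = []
        for s in range(100):  # 100 x 100 = 10,000 trials
            sess = gen_session(100, psycho=psycho, seed=s)
            outcomes += [t.outcome == "correct" for t in sess.trials]
        phat = np.mean(outcomes)
        ci = 3 * np.sqrt(0.25 / len(outcomes))
        assert abs(phat - 0.5) < ci

    def test_full_perseveration_repeats_first_choice(self):
        sess = gen_session(
            30,
            psycho=PsychometricParams(p_omission=0.0, p_perseverate=1.0),
            seed=7,
        )
        choices = [t.chosen_port for t in sess.trials]
        assert len(set(choices)) == 1

    def test_timestamps_follow_trial_structure(self):
        sess = gen_session(40, seed=3)
        prev_end = -np.inf
        for t in sess.trials:
            assert t.init_time_s > prev_end
            assert t.cue_off_s == pytest.approx(t.cue_on_s + t.cue_length_s)
            if t.responded:
                assert t.choice_time_s > t.cue_off_s
            prev_end = t.init_time_s

    def test_error_timeout_delays_next_trial(self):
        # 30 s timeout after errors: the gap after an incorrect trial
        # exceeds the gap after any correct trial
        sess = gen_session(
            60, psycho=PsychometricParams(p_correct=0.5, p_omission=0.0), seed=5
        )
        gaps = {"correct": [], "incorrect": []}
        for a, b in zip(sess.trials, sess.trials[1:]):
            gaps[a.outcome].append(b.init_time_s - a.choice_time_s)
        assert min(gaps["incorrect"]) > max(gaps["correct"])

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            gen_session(10, psycho=PsychometricParams(p_correct=1.5), seed=0)


class TestPhotometry:
    def test_clean_single_transient_recovered_exactly(self):
        sess = gen_session(
            10, psycho=PsychometricParams(p_omission=0.0), seed=1
        )
        amps = np.zeros(10)
        amps[4] = 0.05
        rec, _ = gen_photometry(
            sess, TransientGroundTruth(amplitudes=amps), motion_scale=0.0,
            noise_sd=0.0, seed=0,
        )
        dff = photometry.compute_dff(rec.sig470)
        assert abs(dff.values.max() - 0.05) < 1e-6

    def test_zero_amplitudes_give_flat_dff(self, small_session):
        rec, _ = gen_photometry(
            small_session, TransientGroundTruth(amplitudes=np.zeros(30)),
            motion_scale=0.0, noise_sd=0.0, seed=0,
        )
        dff = photometry.compute_dff(rec.sig470)
        assert np.abs(dff.values).max() < 1e-12

    def test_motion_shared_and_recoverable_by_least_squares(self, small_session):
        rec, truth = gen_photometry(
            small_session, TransientGroundTruth(amplitudes=np.zeros(30)),
            motion_scale=1.0, noise_sd=0.0, seed=2,
        )
        a, b = photometry.isosbestic_fit(rec.sig470, rec.ref405)
        resid = rec.sig470.samples - (a * rec.ref405.samples + b)
        assert np.abs(resid).max() < 1e-9  # pure shared motion cancels exactly

    def test_negative_noise_rejected(self, small_session):
        with pytest.raises(ValueError):
            gen_photometry(
                small_session, TransientGroundTruth(amplitudes=np.zeros(30)),
                noise_sd=-1, seed=0,
            )


class TestLaminar:
    def test_zero_noise_csd_extremum_at_sink_channel(self):
        from attnephys.csd import compute_csd

        sweeps, _ = gen_laminar(8, (6, 10), noise_sd=0.0, seed=0)
        m = compute_csd(sweeps.sweeps[0], sweeps.spacing_um, fs=sweeps.fs)
        row, _col = np.unravel_index(np.argmin(m.values), m.values.shape)
        assert row + 2 == 8  # map row -> 1-based probe channel

    def test_zero_target_csd_gives_flat_map(self):
        from attnephys.csd import compute_csd

        sweeps, _ = gen_laminar(
            8, (), amplitude_per_intensity={100.0: 0.0}, noise_sd=0.0, seed=0
        )
        m = compute_csd(sweeps.sweeps[0], sweeps.spacing_um, fs=sweeps.fs)
        assert np.abs(m.values).max() < 1e-9

    def test_amplitude_curve_monotone_with_intensity(self):
        from attnephys.csd import ComponentWindow, amplitude_curve

        sweeps, _ = gen_laminar(8, (), noise_sd=1e-6, seed=1)
        win = ComponentWindow("sink", 8, 8, 0.02, 0.04, "sink")
        curve = amplitude_curve(sweeps, win)
        mags = [-v for v in curve.values()]  # sink: negative, growing in magnitude
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_edge_sink_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            gen_laminar(1, seed=0)


class TestIpsp:
    def test_release_prob_one_no_failures(self):
        sweeps = gen_ipsp_sweeps(5, 1.0, ipsp_amp_mv=1.0, noise_sd_mv=0.0, seed=0)
        assert intracellular.ipsp_failures(sweeps).per_cell_mean_pct == 0.0

    def test_release_prob_zero_all_failures(self):
        sweeps = gen_ipsp_sweeps(5, 0.0, noise_sd_mv=0.0, seed=0)
        assert intracellular.ipsp_failures(sweeps).per_cell_mean_pct == 100.0

    def test_half_release_within_binomial_99_interval(self):
        sweeps = gen_ipsp_sweeps(50, 0.5, noise_sd_mv=0.02, seed=3)
        pct = intracellular.ipsp_failures(sweeps).per_cell_mean_pct
        half_width = 100 * 2.58 * np.sqrt(0.25 / (50 * 20))
        assert abs(pct - 50.0) < half_width

    def test_train_geometry(self):
        sweeps = gen_ipsp_sweeps(1, 1.0, seed=0)
        ttls = sweeps[0].light_ttl_times_s
        assert ttls.size == 20
        assert np.allclose(np.diff(ttls), 1 / 40.0)
        assert ttls[-1] - ttls[0] == pytest.approx(0.5 - 1 / 40.0)


class TestNoisyCurrent:
    def test_mean_is_dc_level(self):
        cur = gen_noisy_current(duration_s=5.0, seed=0)
        assert abs(cur.samples.mean() - 150.0) < 1.0

    def test_high_frequency_power_suppressed(self):
        cur = gen_noisy_current(duration_s=10.0, seed=1)
        f, pxx = sps.welch(cur.samples - cur.samples.mean(), fs=cur.fs, nperseg=4096)
        total = np.trapezoid(pxx, f)
        above = np.trapezoid(pxx[f > 150], f[f > 150])
        assert above / total <= 0.01

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            gen_noisy_current(fs=500, seed=0)


class TestSpikeSweeps:
    def test_no_inhibition_counts_statistically_equal(self):
        cur = gen_noisy_current(seed=2)
        sweeps = gen_spike_sweeps(cur, 0.0, n_trials=20, seed=2)
        nl = [intracellular.detect_spikes(s.vm).size for s in sweeps if s.condition == "no_light"]
        li = [intracellular.detect_spikes(s.vm).size for s in sweeps if s.condition == "train_40hz"]
        assert abs(np.mean(nl) - np.mean(li)) < 2.0

    def test_half_inhibition_gives_half_reduction(self):
        cur = gen_noisy_current(seed=5)
        sweeps = gen_spike_sweeps(cur, 0.5, n_trials=100, seed=6)
        nl = [intracellular.detect_spikes(s.vm).size for s in sweeps if s.condition == "no_light"]
        li = [intracellular.detect_spikes(s.vm).size for s in sweeps if s.condition == "train_40hz"]
        red = intracellular.spike_reduction(nl, li)["pct"]
        assert abs(red - 50.0) < 5.0

    def test_subthreshold_dc_never_spikes(self):
        from attnephys.signals import ContinuousSignal

        # V_inf = -70 + 200 MOhm * 90 pA = -52 mV, below the -50 mV threshold
        dc = ContinuousSignal(np.full(5000, 90.0), fs=10000.0, units="pA")
        sweeps = gen_spike_sweeps(dc, 0.0, n_trials=2, current_noise_pa=0.0, seed=0)
        assert all(intracellular.detect_spikes(s.vm).size == 0 for s in sweeps)

    def test_lif_rate_in_target_range(self):
        cur = gen_noisy_current(seed=7)
        sweeps = gen_spike_sweeps(cur, 0.0, n_trials=3, seed=7)
        counts = [intracellular.detect_spikes(s.vm).size for s in sweeps]
        assert all(10 <= c <= 40 for c in counts)
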