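"""Synthetic-data generators with machine-readable ground truth.

Every input class the analysis stack consumes can be generated here with
known ground truth: 1/f ECoG with embedded spike-and-wave discharges
(SWDs), dual-wavelength photometry with GCaMP-like transients and shared
motion artifact, 16-channel laminar LFP sweeps built by inverting the
current-source-density operator, 40 Hz IPSP trains with a release
probability, noisy-current-driven leaky integrate-and-fire spiking, and
operant attention-task trial tables with cue-length-dependent accuracy.

Every generator is a pure function of (parameters, seed): the same call
yields bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import (
    ContinuousSignal,
    IntracellularSweep,
    LaminarSweepSet,
    PhotometryRecording,
)
from .trials import SessionTable, TrialRecord

# ---------------------------------------------------------------------------
# ground-truth records


@dataclass
class SwdGroundTruth:
    """Injected SWD events: (start_s, end_s, fundamental_hz) plus amplitudes."""

    events: list[tuple[float, float, float]] = field(default_factory=list)
    amplitudes: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class TransientGroundTruth:
    """Per-trial calcium-transient parameters for the photometry generator.

    Amplitudes are in dF/F units (fractional fluorescence change); the
    transient kernel is a rise/decay double exponential peaking at 1 so the
    stated amplitude is exactly the peak dF/F the pipeline should recover.
    """

    amplitudes: np.ndarray  # one per trial, >= 0
    onset_latency_s: float = 0.1
    rise_tau_s: float = 0.2
    decay_tau_s: float = 0.6
    motion: np.ndarray | None = None          # filled by gen_photometry
    transient_trace: np.ndarray | None = None # filled by gen_photometry

    def __post_init__(self) -> None:
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=np.float64))
        if np.any(self.amplitudes < 0):
            raise ValueError("transient amplitudes must be >= 0")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("transient taus must be > 0")


@dataclass
class PsychometricParams:
    """Outcome model for synthetic sessions.

    ``p_correct`` and ``p_omission`` map cue length (s) to probability; a
    scalar applies to every cue length.  Reaction times are log-normal with
    a higher median on incorrect trials.
    """

    p_correct: dict[float, float] | float = 0.8
    p_omission: dict[float, float] | float = 0.05
    rt_median_correct_s: float = 0.7
    rt_median_incorrect_s: float = 1.2
    rt_sigma: float = 0.4
    p_perseverate: float = 0.0

    def _lookup(self, table, cue: float) -> float:
        p = table if np.isscalar(table) else table[cue]
        if not 0 <= p <= 1:
            raise ValueError(f"probability {p} outside [0, 1]")
        return float(p)

    def correct_prob(self, cue: float) -> float:
        return self._lookup(self.p_correct, cue)

    def omission_prob(self, cue: float) -> float:
        return self._lookup(self.p_omission, cue)


# ---------------------------------------------------------------------------
# ECoG with spike-and-wave discharges


def _one_over_f_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f power spectrum, band-limited 0.1-100 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])  # amplitude 1/sqrt(f) -> power 1/f
    x = np.fft.irfft(spec * shaping, n)
    sos = sps.butter(4, [0.1, min(100.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, x)
    return x / np.std(x)


def _swd_waveform(duration_s: float, f0: float, fs: float, ramp_s: float = 0.2) -> np.ndarray:
    """Harmonic-rich SWD burst: fundamental + half-weight 2nd harmonic +
    a sharp rectified-sinusoid 'spike' component, cosine-ramped."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = np.sin(2 * np.pi * f0 * t) + 0.5 * np.sin(2 * np.pi * 2 * f0 * t)
    spike = np.maximum(0.0, np.sin(2 * np.pi * f0 * t)) ** 4
    wave = wave + 1.5 * (spike - spike.mean())
    env = np.ones(n)
    n_ramp = min(int(round(ramp_s * fs)), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    wave *= env
    rms = np.sqrt(np.mean(wave**2))
    return wave / rms


def gen_ecog(
    duration_s: float,
    fs: float = 1000.0,
    swd_rate_per_min: float = 0.3,
    amplitude_rms: float = 5.0,
    f0_range: tuple[float, float] = (7.0, 10.0),
    dur_range: tuple[float, float] = (2.0, 30.0),
    seed: int = 0,
) -> tuple[ContinuousSignal, SwdGroundTruth]:
    """Synthetic ECoG: band-limited 1/f background plus embedded SWDs.

    SWD count is Poisson at ``swd_rate_per_min``; events are placed without
    overlap, with fundamental frequency uniform in ``f0_range`` and duration
    uniform in ``dur_range``.  ``amplitude_rms`` scales SWD RMS amplitude in
    units of the background RMS (default 5x).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    if fs < 200:
        raise ValueError("fs must be >= 200 Hz")
    if swd_rate_per_min < 0:
        raise ValueError("swd_rate_per_min must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    background_rms = 1e-4  # 100 uV in volts
    x = _one_over_f_noise(n, fs, rng) * background_rms

    truth = SwdGroundTruth()
    n_events = rng.poisson(swd_rate_per_min * duration_s / 60.0)
    margin = 2.0
    placed: list[tuple[float, float]] = []
    for _ in range(n_events):
        dur = float(rng.uniform(*dur_range))
        f0 = float(rng.uniform(*f0_range))
        for _attempt in range(1000):
            start = float(rng.uniform(margin, max(margin, duration_s - dur - margin)))
            if all(start > e + 1.0 or start + dur < s - 1.0 for s, e in placed):
                break
        else:
            continue  # session too crowded; drop the event
        placed.append((start, start + dur))
        amp = amplitude_rms * background_rms
        wave = _swd_waveform(dur, f0, fs) * amp
        i0 = int(round(start * fs))
        x[i0 : i0 + wave.size] += wave[: max(0, n - i0)]
        truth.events.append((start, start + dur, f0))
        truth.amplitudes.append(amp)
    order = np.argsort([e[0] for e in truth.events]) if truth.events else []
    truth.events = [truth.events[i] for i in order]
    truth.amplitudes = [truth.amplitudes[i] for i in order]
    sig = ContinuousSignal(samples=x, fs=fs, label="ecog", units="V")
    return sig, truth


# ---------------------------------------------------------------------------
# behavioral sessions


def gen_session(
    n_trials: int,
    task: str = "AET",
    cue_lengths: tuple[float, ...] = (5.0, 2.0, 0.5),
    psycho: PsychometricParams | None = None,
    seed: int = 0,
    delays: tuple[float, ...] = (3.0, 4.0, 5.0),
    animal_id: str = "sim",
    genotype: str = "synthetic",
    day: str = "1",
) -> SessionTable:
    """Synthetic operant session with pseudorandom cue lengths and sides.

    Cue lengths and correct sides are assigned in near-equal counts then
    shuffled; outcomes follow the :class:`PsychometricParams` model.  An
    incorrect choice is followed by a 30 s timeout before the next trial
    can start.  VDST trials draw a pre-cue delay from ``delays``.
    """
    if not 1 <= n_trials <= 100:
        raise ValueError("n_trials must be in [1, 100]")
    if not cue_lengths:
        raise ValueError("cue_lengths must be non-empty")
    psycho = psycho or PsychometricParams()
    if not 0 <= psycho.p_perseverate <= 1:
        raise ValueError("p_perseverate outside [0, 1]")
    rng = np.random.default_rng(seed)

    cues = np.tile(np.asarray(cue_lengths, float), n_trials // len(cue_lengths) + 1)[:n_trials]
    rng.shuffle(cues)
    sides = np.tile(np.array(["L", "R"]), n_trials // 2 + 1)[:n_trials]
    rng.shuffle(sides)

    trials: list[TrialRecord] = []
    t = 30.0
    prev_choice: str | None = None
    for i in range(n_trials):
        cue = float(cues[i])
        correct = str(sides[i])
        delay = float(rng.choice(delays)) if task == "VDST" else 0.0
        init = t
        cue_on = init + delay
        cue_off = cue_on + cue

        omit = rng.random() < psycho.omission_prob(cue)
        if omit:
            chosen, outcome, choice_time = "none", "omission", None
        else:
            if prev_choice is not None and rng.random() < psycho.p_perseverate:
                chosen = prev_choice
            else:
                is_correct = rng.random() < psycho.correct_prob(cue)
                chosen = correct if is_correct else ("L" if correct == "R" else "R")
            outcome = "correct" if chosen == correct else "incorrect"
            median = (
                psycho.rt_median_correct_s
                if outcome == "correct"
                else psycho.rt_median_incorrect_s
            )
            rt = float(np.exp(np.log(median) + psycho.rt_sigma * rng.standard_normal()))
            rt = min(max(rt, 0.05), 4.9)  # responded trials answer within the 5 s limit
            choice_time = cue_off + rt
            prev_choice = chosen

        trials.append(
            TrialRecord(
                index=i,
                task=task,
                cue_length_s=cue,
                delay_s=delay,
                correct_port=correct,
                chosen_port=chosen,
                init_time_s=init,
                cue_on_s=cue_on,
                cue_off_s=cue_off,
                choice_time_s=choice_time,
                outcome=outcome,
            )
        )
        end = choice_time if choice_time is not None else cue_off + 5.0
        iti = 2.0 + float(rng.exponential(3.0))
        if outcome == "incorrect":
            iti += 30.0  # timeout after errors
        t = end + iti

    duration = min(t + 10.0, 4800.0)
    return SessionTable(
        trials=trials,
        session_duration_s=duration,
        animal_id=animal_id,
        genotype=genotype,
        day=day,
    )


# ---------------------------------------------------------------------------
# fiber photometry


def _transient_kernel(fs: float, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Rise/decay double exponential, peak-normalized to exactly 1."""
    t = np.arange(0, 8 * decay_tau, 1 / fs)
    k = np.exp(-t / decay_tau) - np.exp(-t / rise_tau)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate transient kernel (rise_tau >= decay_tau?)")
    return k / peak


def gen_photometry(
    session: SessionTable,
    truth: TransientGroundTruth,
    motion_scale: float = 0.5,
    noise_sd: float = 0.01,
    fs: float = 20.0,
    seed: int = 0,
) -> tuple[PhotometryRecording, TransientGroundTruth]:
    """Dual-wavelength photometry for a session with known transients.

    sig470 = B470 * (1 + transients) + motion_scale * motion + noise
    ref405 = B405 + motion_scale * motion + noise  (no transients)

    The shared motion artifact is low-passed Gaussian noise (unit SD); TTLs
    mark trial initiations.  Returns the recording and the ground truth with
    ``motion`` and ``transient_trace`` (dF/F units) filled in.
    """
    if len(session) == 0:
        raise ValueError("session must be non-empty")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(session.session_duration_s * fs))
    t_axis = np.arange(n) / fs

    amps = truth.amplitudes
    if amps.size == 1:
        amps = np.full(len(session), float(amps[0]))
    elif amps.size != len(session):
        raise ValueError("need one transient amplitude per trial (or a scalar)")

    kernel = _transient_kernel(fs, truth.rise_tau_s, truth.decay_tau_s)
    x = np.zeros(n)
    for trial, amp in zip(session.trials, amps):
        onset = trial.cue_on_s + truth.onset_latency_s
        i0 = int(round(onset * fs))
        if i0 >= n:
            continue
        seg = kernel[: n - i0]
        x[i0 : i0 + seg.size] += amp * seg

    motion = rng.standard_normal(n)
    sos = sps.butter(2, min(1.0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
    motion = sps.sosfiltfilt(sos, motion)
    motion /= np.std(motion)

    b470, b405 = 100.0, 50.0
    noise470 = rng.normal(0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    noise405 = rng.normal(0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    sig470 = b470 * (1 + x) + motion_scale * motion + noise470
    ref405 = b405 + motion_scale * motion + noise405

    ttls = np.array(
        [t.init_time_s for t in session.trials if t.init_time_s is not None], float
    )
    rec = PhotometryRecording(
        sig470=ContinuousSignal(sig470, fs=fs, label="470nm", units="au"),
        ref405=ContinuousSignal(ref405, fs=fs, label="405nm", units="au"),
        trial_ttl_times_s=ttls,
    )
    truth_out = TransientGroundTruth(
        amplitudes=amps,
        onset_latency_s=truth.onset_latency_s,
        rise_tau_s=truth.rise_tau_s,
        decay_tau_s=truth.decay_tau_s,
        motion=motion,
        transient_trace=x,
    )
    return rec, truth_out


# ---------------------------------------------------------------------------
# laminar LFP sweeps (CSD forward model)


def gen_laminar(
    sink_channel: int,
    source_channels: tuple[int, ...] = (),
    amplitude_per_intensity: dict[float, float] | None = None,
    latency_s: float = 0.004,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_channels: int = 16,
    spacing_um: float = 100.0,
    fs: float = 10000.0,
    sweep_len_s: float = 0.1,
    stim_onset_s: float = 0.02,
    n_trials_per_intensity: int = 10,
    kernel_tau_s: float = 0.004,
) -> tuple[LaminarSweepSet, np.ndarray]:
    """Laminar LFP sweeps whose CSD is known by construction.

    A target CSD profile (sink of -1 at ``sink_channel``, sources of +0.5 at
    ``source_channels``; channels 1-based) with an alpha-function time course
    is inverted by double cumulative summation across depth, so the CSD
    operator recovers it exactly at zero noise.  A random per-time linear
    depth profile is added (invisible to the CSD).  Returns the sweep set and
    the injected CSD (channel x time, V/mm^2, unit amplitude).
    """
    if not 2 <= sink_channel <= n_channels - 1:
        raise ValueError(
            f"sink_channel must be an interior channel (2..{n_channels - 1}); "
            "CSD is undefined on edge channels"
        )
    for src in source_channels:
        if not 2 <= src <= n_channels - 1:
            raise ValueError("source channels must be interior channels")
    amplitude_per_intensity = amplitude_per_intensity or {
        100.0: 1.0, 200.0: 2.0, 300.0: 3.0, 400.0: 4.0, 500.0: 5.0
    }
    rng = np.random.default_rng(seed)
    n = int(round(sweep_len_s * fs))
    t = np.arange(n) / fs

    # alpha-function time course, peak 1 at stim_onset + latency + tau
    tt = t - stim_onset_s - latency_s
    kernel = np.where(tt > 0, (tt / kernel_tau_s) * np.exp(1 - tt / kernel_tau_s), 0.0)

    profile = np.zeros(n_channels)
    profile[sink_channel - 1] = -1.0  # sinks are negative
    for src in source_channels:
        profile[src - 1] += 0.5
    csd_truth = np.outer(profile, kernel)  # V/mm^2 at unit amplitude

    h_mm = spacing_um / 1000.0
    sweeps: list[np.ndarray] = []
    intensities: list[float] = []
    for intensity in sorted(amplitude_per_intensity):
        amp = amplitude_per_intensity[intensity]
        for _ in range(n_trials_per_intensity):
            # double cumulative sum inverts the second difference:
            # (cumsum2 u)[i+1] - 2(...)[i] + (...)[i-1] = u[i+1], so the
            # CSD injected at interior channel i must be placed at u[i+1]
            u = np.zeros((n_channels, n))
            u[2:] = -(h_mm**2) * amp * csd_truth[1:-1]
            v = np.cumsum(np.cumsum(u, axis=0), axis=0)
            a = rng.normal(0, 1e-5, n)
            b = rng.normal(0, 1e-5, n)
            v = v + a + b * np.arange(n_channels)[:, None]
            if noise_sd > 0:
                v = v + rng.normal(0, noise_sd, v.shape)
            sweeps.append(v)
            intensities.append(float(intensity))
    sweep_set = LaminarSweepSet(
        sweeps=sweeps,
        fs=fs,
        stim_intensity_ua=np.array(intensities),
        stim_onset_s=stim_onset_s,
        n_channels=n_channels,
        spacing_um=spacing_um,
    )
    return sweep_set, csd_truth


# ---------------------------------------------------------------------------
# intracellular: IPSP trains and spiking sweeps


def _ipsp_kernel(fs: float, rise_tau_s: float, decay_tau_s: float) -> np.ndarray:
    t = np.arange(0, 6 * decay_tau_s, 1 / fs)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    return k / k.max()


def gen_ipsp_sweeps(
    n_trials: int,
    p_release: float,
    ipsp_amp_mv: float = 1.0,
    tau_s: float = 0.008,
    noise_sd_mv: float = 0.02,
    seed: int = 0,
    fs: float = 10000.0,
    sweep_len_s: float = 1.5,
    train_start_s: float = 0.5,
    train_hz: float = 40.0,
    n_pulses: int = 20,
) -> list[IntracellularSweep]:
    """40 Hz optogenetic IPSP trains with Bernoulli release.

    Each of the 20 TTL pulses (0.5 s train at 40 Hz) independently evokes a
    hyperpolarizing IPSP of peak amplitude ``ipsp_amp_mv`` with probability
    ``p_release``, else nothing; Gaussian voltage noise is added.
    """
    if not 0 <= p_release <= 1:
        raise ValueError("p_release must be in [0, 1]")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(round(sweep_len_s * fs))
    ttl_times = train_start_s + np.arange(n_pulses) / train_hz
    kernel = _ipsp_kernel(fs, 0.001, tau_s)
    sweeps = []
    for _ in range(n_trials):
        vm = np.full(n, -70.0)
        if noise_sd_mv > 0:
            vm += rng.normal(0, noise_sd_mv, n)
        released = rng.random(n_pulses) < p_release
        for ttl, rel in zip(ttl_times, released):
            if not rel:
                continue
            i0 = int(round(ttl * fs))
            seg = kernel[: n - i0]
            vm[i0 : i0 + seg.size] -= ipsp_amp_mv * seg
        sweeps.append(
            IntracellularSweep(
                vm=ContinuousSignal(vm, fs=fs, label="vm", units="mV"),
                light_ttl_times_s=ttl_times,
                condition="train_40hz",
            )
        )
    return sweeps


def gen_noisy_current(
    duration_s: float = 0.5,
    fs: float = 10000.0,
    seed: int = 0,
    dc_pa: float = 150.0,
    noise_sd_pa: float = 10.0,
    alpha_tau_s: float = 0.003,
    lowpass_hz: float = 100.0,
) -> ContinuousSignal:
    """Naturalistic noisy current injection.

    150 pA DC plus white Gaussian noise (SD 10 pA) convolved with a 3 ms
    alpha kernel (unit DC gain) and low-passed at 100 Hz.
    """
    if fs < 1000:
        raise ValueError("fs must be >= 1 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    noise = rng.normal(0, noise_sd_pa, n)
    t = np.arange(0, 8 * alpha_tau_s, 1 / fs)
    alpha = (t / alpha_tau_s) * np.exp(1 - t / alpha_tau_s)
    alpha /= alpha.sum()  # unit area: preserves the DC level
    noise = sps.fftconvolve(noise, alpha, mode="full")[:n]
    sos = sps.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
    noise = sps.sosfiltfilt(sos, noise)
    return ContinuousSignal(dc_pa + noise, fs=fs, label="stim", units="pA")


@dataclass
class LifParams:
    """Leaky integrate-and-fire membrane; R*I uses R in Mohm, I in pA."""

    tau_m_s: float = 0.020
    r_mohm: float = 200.0
    v_rest_mv: float = -70.0
    v_thresh_mv: float = -50.0
    v_reset_mv: float = -60.0
    refractory_s: float = 0.002
    spike_peak_mv: float = 30.0


def gen_spike_sweeps(
    current: ContinuousSignal,
    inhibition_fraction: float = 0.5,
    n_trials: int = 5,
    lif: LifParams | None = None,
    seed: int = 0,
    current_noise_pa: float = 5.0,
) -> list[IntracellularSweep]:
    """LIF spiking sweeps driven by a (frozen) noisy current, with and
    without 40 Hz inhibition.

    Returns ``n_trials`` no-light sweeps then ``n_trials`` light sweeps.  In
    light sweeps each threshold crossing is independently suppressed with
    probability ``inhibition_fraction`` — the membrane is reset (the
    hyperpolarization) but no spike is emitted — so the expected spike count
    drops by that fraction.
    """
    if not 0 <= inhibition_fraction <= 1:
        raise ValueError("inhibition_fraction must be in [0, 1]")
    lif = lif or LifParams()
    rng = np.random.default_rng(seed)
    fs = current.fs
    dt = 1 / fs
    n = current.samples.size
    refr_n = max(1, int(round(lif.refractory_s * fs)))
    ttl_times = np.arange(0, current.duration_s - 1e-9, 1 / 40.0)

    sweeps: list[IntracellularSweep] = []
    for cond in ("no_light", "train_40hz"):
        for _ in range(n_trials):
            i_trial = current.samples + (
                rng.normal(0, current_noise_pa, n) if current_noise_pa > 0 else 0.0
            )
            vm = np.empty(n)
            v = lif.v_rest_mv
            refr_left = 0
            for i in range(n):
                if refr_left > 0:
                    refr_left -= 1
                    v = lif.v_reset_mv
                    vm[i] = v
                    continue
                # R [Mohm] * I [pA] * 1e-3 -> mV
                dv = (-(v - lif.v_rest_mv) + lif.r_mohm * i_trial[i] * 1e-3) * dt / lif.tau_m_s
                v += dv
                if v > lif.v_thresh_mv:
                    suppressed = (
                        cond == "train_40hz" and rng.random() < inhibition_fraction
                    )
                    vm[i] = lif.v_reset_mv if suppressed else lif.spike_peak_mv
                    v = lif.v_reset_mv
                    refr_left = refr_n
                else:
                    vm[i] = v
            sweeps.append(
                IntracellularSweep(
                    vm=ContinuousSignal(vm, fs=fs, label="vm", units="mV"),
                    stim_current=current,
                    light_ttl_times_s=ttl_times if cond == "train_40hz" else np.empty(0),
                    condition=cond,
                )
            )
    return sweeps
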