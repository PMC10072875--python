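"""Morlet continuous-wavelet spectrograms and band-power extraction.

The spectral stack mirrors a standard rodent-ECoG workflow: a complex
Morlet CWT (center frequency omega0 = 6) on a log-spaced frequency grid,
squared-modulus power, optional peak normalization + log10 transform, and
averaging within named frequency bands (theta-like 7-10 Hz fundamental and
beta 10-20 Hz harmonic bands for spike-and-wave activity, plus 4-8, 8-12,
12-30, 30-50 and 60-90 Hz bands).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .signals import ContinuousSignal

OMEGA0_DEFAULT = 6.0
_LOG_FLOOR = 1e-15  # on peak-normalized power, keeps log10 finite


@dataclass
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not 0 < self.lo_hz < self.hi_hz:
            raise ValueError(f"band {self.name}: need 0 < lo < hi")


#: Fundamental (theta-like) and 2nd-harmonic (beta) SWD bands, plus the
#: broader band set used for cue-period power.
DEFAULT_BANDS: dict[str, BandDefinition] = {
    b.name: b
    for b in [
        BandDefinition("theta_swd", 7.0, 10.0),
        BandDefinition("beta_swd", 10.0, 20.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 12.0),
        BandDefinition("beta", 12.0, 30.0),
        BandDefinition("low_gamma", 30.0, 50.0),
        BandDefinition("high_gamma", 60.0, 90.0),
    ]
}


@dataclass
class Spectrogram:
    power: np.ndarray      # (n_freqs, n_times), >= 0
    freqs_hz: np.ndarray   # strictly increasing
    times_s: np.ndarray    # uniform
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # log-transformed spectrograms are signed; raw power must be >= 0
        if self.params.get("normalized", "none") == "none" and np.any(self.power < 0):
            raise ValueError("power must be non-negative")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("freqs must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


def default_freq_grid(
    lo_hz: float = 1.0, hi_hz: float = 100.0, n_voices: int = 48
) -> np.ndarray:
    """Log-spaced CWT frequency grid (48 voices over 1-100 Hz by default)."""
    return np.geomspace(lo_hz, hi_hz, n_voices)


def _morlet_wavelet(omega0: float) -> pywt.ContinuousWavelet:
    # pywt cmorB-C: exp(2i*pi*C*t) exp(-t^2/B); omega0 maps to C = omega0/(2*pi)
    # and the unit-variance Gaussian envelope to B = 2.
    fc = omega0 / (2 * np.pi)
    return pywt.ContinuousWavelet(f"cmor2.0-{fc:.10f}")


def decimate(signal: ContinuousSignal, target_fs: float) -> ContinuousSignal:
    """Anti-aliased decimation to (approximately) ``target_fs``."""
    factor = int(round(signal.fs / target_fs))
    if factor <= 1:
        return signal
    samples = sps.decimate(signal.samples, factor, ftype="fir", zero_phase=True)
    return ContinuousSignal(
        samples, fs=signal.fs / factor, t0=signal.t0, label=signal.label, units=signal.units
    )


def morlet_cwt(
    signal: ContinuousSignal,
    freqs_hz: np.ndarray | None = None,
    omega0: float = OMEGA0_DEFAULT,
) -> Spectrogram:
    """Complex-Morlet CWT power spectrogram.

    Power is the squared modulus of the wavelet coefficients; the time axis
    matches the input sample times.  Frequencies above Nyquist raise; the
    record must cover at least 3 cycles of the lowest requested frequency.
    Edge samples within one wavelet e-folding time of the borders are
    retained but flagged through ``params['coi_margin_s']``.
    """
    freqs = np.sort(np.asarray(freqs_hz if freqs_hz is not None else default_freq_grid(), float))
    fs = signal.fs
    if freqs.max() >= fs / 2:
        raise ValueError(
            f"requested frequency {freqs.max():g} Hz is at/above Nyquist ({fs / 2:g} Hz)"
        )
    if signal.duration_s < 3.0 / freqs.min():
        raise ValueError(
            f"signal too short: need >= 3 cycles of {freqs.min():g} Hz "
            f"({3.0 / freqs.min():g} s), have {signal.duration_s:g} s"
        )
    wavelet = _morlet_wavelet(omega0)
    dt = 1.0 / fs
    scales = pywt.frequency2scale(wavelet, freqs * dt)
    n = signal.samples.size
    power = np.empty((freqs.size, n))
    # one scale at a time keeps peak memory at a single complex row
    for i, sc in enumerate(scales):
        coef, _ = pywt.cwt(signal.samples, [sc], wavelet, sampling_period=dt, method="fft")
        power[i] = np.abs(coef[0]) ** 2
    # e-folding time of the Gaussian envelope at the lowest frequency
    coi_margin = float(np.sqrt(2) * scales.max() * dt)
    return Spectrogram(
        power=power,
        freqs_hz=freqs,
        times_s=signal.t0 + np.arange(n) * dt,
        params={"omega0": omega0, "fs": fs, "coi_margin_s": coi_margin, "normalized": "none"},
    )


def peak_normalize_log10(spec: Spectrogram, per_frequency: bool = False) -> Spectrogram:
    """Divide power by its global (or per-frequency-row) maximum, log10.

    The global maximum of the output is exactly 0; all other values are
    negative.  Values are floored so an all-quiet bin cannot produce -inf.
    """
    ref = spec.power.max(axis=1, keepdims=True) if per_frequency else spec.power.max()
    if np.any(ref <= 0):
        raise ValueError("cannot peak-normalize an all-zero spectrogram")
    norm = np.log10(np.maximum(spec.power / ref, _LOG_FLOOR))
    return Spectrogram(
        power=norm,
        freqs_hz=spec.freqs_hz,
        times_s=spec.times_s,
        params={**spec.params, "normalized": "peak_log10"},
    )


def band_power(
    spec: Spectrogram,
    band: BandDefinition,
    normalize: str = "none",
    per_frequency: bool = False,
) -> ContinuousSignal:
    """Mean power across in-band frequency rows, per time point.

    ``normalize='peak_log10'`` first divides the spectrogram by its global
    maximum and log10-transforms (values <= 0) before band averaging.
    """
    if normalize not in ("none", "peak_log10"):
        raise ValueError(f"unknown normalization {normalize!r}")
    rows = (spec.freqs_hz >= band.lo_hz) & (spec.freqs_hz <= band.hi_hz)
    if not rows.any():
        raise ValueError(
            f"band {band.name} ({band.lo_hz}-{band.hi_hz} Hz) contains no grid frequencies"
        )
    values = spec.power
    if normalize == "peak_log10":
        values = peak_normalize_log10(spec, per_frequency=per_frequency).power
    trace = values[rows].mean(axis=0)
    fs = 1.0 / spec.dt
    units = "log10(power/peak)" if normalize == "peak_log10" else "power"
    return ContinuousSignal(
        trace, fs=fs, t0=float(spec.times_s[0]), label=f"band:{band.name}", units=units
    )


@dataclass
class AlignedPower:
    """Event-aligned per-trial power traces with group summaries."""

    traces: np.ndarray            # (n_trials, n_times)
    time_s: np.ndarray            # relative to the event
    labels: list                  # one label (hashable) per kept trial
    kept_events_s: np.ndarray
    dropped_events_s: np.ndarray

    def group_stats(self) -> dict:
        """Per-label mean and variance traces: label -> (mean, var, n)."""
        out = {}
        for lab in sorted(set(self.labels), key=repr):
            rows = self.traces[[i for i, l in enumerate(self.labels) if l == lab]]
            out[lab] = (rows.mean(axis=0), rows.var(axis=0, ddof=0), rows.shape[0])
        return out


def align_power(
    power: ContinuousSignal,
    events_s: np.ndarray,
    window: tuple[float, float] = (1.0, 5.0),
    labels: list | None = None,
) -> AlignedPower:
    """Segment a band-power trace around events.

    ``window = (pre_s, post_s)`` spans [-pre, post) around each event.
    Events whose window falls outside the recording are dropped with a
    warning, not an error.
    """
    events = np.asarray(events_s, float)
    labels = list(labels) if labels is not None else [None] * events.size
    if len(labels) != events.size:
        raise ValueError("one label per event required")
    pre, post = window
    n_pre = int(round(pre * power.fs))
    n_post = int(round(post * power.fs))
    rows, kept, kept_labels, dropped = [], [], [], []
    for ev, lab in zip(events, labels):
        c = power.index_at(ev)
        if c - n_pre < 0 or c + n_post > power.samples.size:
            dropped.append(ev)
            continue
        rows.append(power.samples[c - n_pre : c + n_post])
        kept.append(ev)
        kept_labels.append(lab)
    if dropped:
        warnings.warn(
            f"align_power: dropped {len(dropped)} event(s) too close to the record edge",
            stacklevel=2,
        )
    time_axis = (np.arange(n_pre + n_post) - n_pre) / power.fs
    return AlignedPower(
        traces=np.array(rows) if rows else np.empty((0, n_pre + n_post)),
        time_s=time_axis,
        labels=kept_labels,
        kept_events_s=np.asarray(kept),
        dropped_events_s=np.asarray(dropped),
    )


def stim_band_response(
    power: ContinuousSignal,
    train_onsets_s: np.ndarray,
    train_len_s: float,
    baseline_s: float = 0.5,
) -> list[tuple[float, float]]:
    """Per-train (baseline, stimulation) mean band power.

    Baseline is the ``baseline_s`` (default 0.5 s) window immediately before
    each train onset; stimulation is [onset, onset + train_len).  Trains
    must not overlap.
    """
    onsets = np.sort(np.asarray(train_onsets_s, float))
    if np.any(np.diff(onsets) < train_len_s):
        raise ValueError("stimulus trains overlap")
    pairs = []
    for onset in onsets:
        i0 = power.index_at(onset)
        ib = power.index_at(onset - baseline_s)
        i1 = power.index_at(onset + train_len_s)
        if ib < 0 or i1 > power.samples.size:
            raise ValueError(f"train at {onset:g} s extends outside the recording")
        pairs.append(
            (float(power.samples[ib:i0].mean()), float(power.samples[i0:i1].mean()))
        )
    return pairs
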