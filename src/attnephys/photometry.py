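"""Fiber-photometry processing: motion correction, dF/F, trial alignment.

The isosbestic 405 nm channel carries motion artifact but no calcium
signal; it is scaled to the 470 nm GCaMP channel by least squares and
subtracted.  dF/F is (f - median(f)) / median(f) with the median taken
over the whole session.  Trials are aligned to cue onset with a 1 s
baseline window immediately before the cue, and per-trial features (peak,
average, time-to-peak) plus a summary-statistic feature vector for
decoding are extracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .signals import ContinuousSignal, PhotometryRecording
from .trials import SessionTable

#: summary statistics computed over each analysis window for decoding
FEATURE_STATS = (
    "mean", "median", "sd", "min", "max", "range",
    "skewness", "kurtosis", "slope", "integral", "time_to_peak",
)


@dataclass
class DffTrace:
    values: np.ndarray
    fs: float
    t0: float = 0.0
    fit: tuple[float, float, float] | None = None  # (scale a, offset b, residual RMS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dF/F contains non-finite values")

    def index_at(self, t_s: float) -> int:
        return int(round((t_s - self.t0) * self.fs))


def deinterleave(raw: ContinuousSignal, phase: int = 0) -> PhotometryRecording:
    """Split an interleaved 2x-rate acquisition into 470/405 channels.

    Even samples go to one wavelength and odd samples to the other, each at
    half the raw rate and time-stamped at its true acquisition time.
    ``phase=0`` assigns even samples to 470 nm; ``phase=1`` swaps.  An odd
    trailing sample is dropped with a warning.
    """
    if phase not in (0, 1):
        raise ValueError("phase must be 0 or 1")
    x = raw.samples
    if x.size % 2:
        warnings.warn("deinterleave: odd-length input, dropping last sample", stacklevel=2)
        x = x[:-1]
    even = x[0::2]
    odd = x[1::2]
    fs_out = raw.fs / 2
    ch_even = ContinuousSignal(even, fs=fs_out, t0=raw.t0, label="470nm", units=raw.units)
    ch_odd = ContinuousSignal(
        odd, fs=fs_out, t0=raw.t0 + 1 / raw.fs, label="405nm", units=raw.units
    )
    if phase == 0:
        sig470, ref405 = ch_even, ch_odd
    else:
        ch_even.label, ch_odd.label = "405nm", "470nm"
        sig470, ref405 = ch_odd, ch_even
    return PhotometryRecording(sig470=sig470, ref405=ref405)


def motion_correct(sig470: ContinuousSignal, ref405: ContinuousSignal) -> ContinuousSignal:
    """Least-squares isosbestic subtraction.

    Fits a*ref + b to the 470 nm signal, subtracts the scaled reference and
    restores the signal mean (so the downstream median normalization stays
    well defined).  The fit (a, b, residual RMS) is recorded on the output's
    label metadata via the returned signal's ``units`` staying unchanged and
    the fit retrievable from :func:`isosbestic_fit`.
    """
    a, b = isosbestic_fit(sig470, ref405)
    resid = sig470.samples - (a * ref405.samples + b)
    corrected = resid + sig470.samples.mean()
    return ContinuousSignal(
        corrected, fs=sig470.fs, t0=sig470.t0, label="470nm_corrected", units=sig470.units
    )


def isosbestic_fit(sig470: ContinuousSignal, ref405: ContinuousSignal) -> tuple[float, float]:
    """Closed-form least-squares (a, b) for sig ~= a*ref + b."""
    sig = sig470.samples
    ref = ref405.samples
    if sig.size != ref.size:
        raise ValueError("channels must have equal length")
    if sig.size < 10:
        raise ValueError("need at least 10 samples for the isosbestic fit")
    var = np.var(ref)
    if var == 0:
        raise ValueError("isosbestic reference has zero variance; cannot fit")
    a = float(np.cov(ref, sig, bias=True)[0, 1] / var)
    b = float(sig.mean() - a * ref.mean())
    return a, b


def compute_dff(
    trace: ContinuousSignal, fit: tuple[float, float, float] | None = None
) -> DffTrace:
    """dF/F = (f - median(f)) / median(f), median over the whole session."""
    med = float(np.median(trace.samples))
    if med <= 0:
        raise ValueError(
            f"non-positive session median ({med:g}); upstream correction is broken"
        )
    dff = (trace.samples - med) / med
    return DffTrace(values=dff, fs=trace.fs, t0=trace.t0, fit=fit)


def process_recording(rec: PhotometryRecording, correct_motion: bool = True) -> DffTrace:
    """Convenience chain: (optional) motion correction then dF/F."""
    if correct_motion:
        a, b = isosbestic_fit(rec.sig470, rec.ref405)
        resid = rec.sig470.samples - (a * rec.ref405.samples + b)
        corrected = motion_correct(rec.sig470, rec.ref405)
        return compute_dff(corrected, fit=(a, b, float(np.sqrt(np.mean(resid**2)))))
    return compute_dff(rec.sig470)


@dataclass
class TrialAlignedTraces:
    """Trial x time dF/F matrix aligned to cue onset.

    The baseline window is exactly the 1 s immediately before cue onset;
    the cue window is [0, cue_length) per trial.
    """

    traces: np.ndarray             # (n_trials, n_times)
    time_s: np.ndarray             # relative to cue onset
    cue_lengths_s: np.ndarray
    outcomes: list[str]
    fs: float
    pre_s: float = 1.0
    post_s: float = 5.0
    dropped_trials: list[int] = field(default_factory=list)


def segment_trials(
    dff: DffTrace,
    session: SessionTable,
    pre_s: float = 1.0,
    post_s: float = 5.0,
) -> TrialAlignedTraces:
    """One row per trial, [-pre_s, post_s) around cue onset.

    Rows carry cue-length and outcome labels; trials whose window leaves
    the recording are dropped with a warning.
    """
    if len(session) == 0:
        raise ValueError("empty session")
    n_pre = int(round(pre_s * dff.fs))
    n_post = int(round(post_s * dff.fs))
    rows, cues, outcomes, dropped = [], [], [], []
    for t in session.trials:
        if t.cue_on_s is None:
            dropped.append(t.index)
            continue
        c = dff.index_at(t.cue_on_s)
        if c - n_pre < 0 or c + n_post > dff.values.size:
            dropped.append(t.index)
            continue
        rows.append(dff.values[c - n_pre : c + n_post])
        cues.append(t.cue_length_s)
        outcomes.append(t.outcome)
    if dropped:
        warnings.warn(
            f"segment_trials: dropped {len(dropped)} trial(s) outside the recording",
            stacklevel=2,
        )
    time_axis = (np.arange(n_pre + n_post) - n_pre) / dff.fs
    return TrialAlignedTraces(
        traces=np.array(rows) if rows else np.empty((0, n_pre + n_post)),
        time_s=time_axis,
        cue_lengths_s=np.asarray(cues),
        outcomes=outcomes,
        fs=dff.fs,
        pre_s=pre_s,
        post_s=post_s,
        dropped_trials=dropped,
    )


def _moment_or_zero(fn, seg: np.ndarray, min_n: int, constant: bool) -> float:
    if seg.size < min_n or constant:
        return 0.0
    with warnings.catch_warnings():
        # scipy warns about precision on near-constant data; 0-ish is fine here
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(fn(seg))


def _window_stats(seg: np.ndarray, fs: float) -> dict[str, float]:
    t = np.arange(seg.size) / fs
    slope = float(np.polyfit(t, seg, 1)[0]) if seg.size > 1 else 0.0
    constant = seg.std(ddof=0) == 0  # moments undefined on a flat segment
    return {
        "mean": float(seg.mean()),
        "median": float(np.median(seg)),
        "sd": float(seg.std(ddof=0)),
        "min": float(seg.min()),
        "max": float(seg.max()),
        "range": float(seg.max() - seg.min()),
        "skewness": _moment_or_zero(spstats.skew, seg, 3, constant),
        "kurtosis": _moment_or_zero(spstats.kurtosis, seg, 4, constant),
        "slope": slope,
        "integral": float(np.trapezoid(seg, dx=1 / fs)),
        "time_to_peak": float(np.argmax(seg) / fs),
    }


def trial_features(aligned: TrialAlignedTraces) -> pd.DataFrame:
    """Per-trial photometry features.

    Columns: ``baseline_mean`` (mean over [-1, 0)), ``cue_mean`` (mean over
    [0, cue_length)), ``peak_raw`` (max over cue window), ``peak_amplitude``
    (baseline-subtracted peak), ``time_to_peak_s``, the outcome/cue labels,
    and ``base_<stat>`` / ``cue_<stat>`` summary-statistic columns used for
    decoding.
    """
    fs = aligned.fs
    n_pre = int(round(aligned.pre_s * fs))
    base_lo = n_pre - int(round(1.0 * fs))  # exactly the second before the cue
    if base_lo < 0:
        raise ValueError("aligned traces do not include a full 1 s baseline")
    records = []
    for i in range(aligned.traces.shape[0]):
        trace = aligned.traces[i]
        cue_len = float(aligned.cue_lengths_s[i])
        n_cue = int(round(cue_len * fs))
        if n_cue > aligned.traces.shape[1] - n_pre:
            raise ValueError(
                f"cue window ({cue_len:g} s) exceeds the stored post window "
                f"({aligned.post_s:g} s)"
            )
        baseline = trace[base_lo:n_pre]
        cue_seg = trace[n_pre : n_pre + n_cue]
        baseline_mean = float(baseline.mean())
        peak_raw = float(cue_seg.max())
        rec = {
            "trial": i,
            "cue_length_s": cue_len,
            "outcome": aligned.outcomes[i],
            "baseline_mean": baseline_mean,
            "cue_mean": float(cue_seg.mean()),
            "peak_raw": peak_raw,
            "peak_amplitude": peak_raw - baseline_mean,
            "time_to_peak_s": float(np.argmax(cue_seg) / fs),
        }
        for name, val in _window_stats(baseline, fs).items():
            rec[f"base_{name}"] = val
        for name, val in _window_stats(cue_seg, fs).items():
            rec[f"cue_{name}"] = val
        records.append(rec)
    return pd.DataFrame.from_records(records)
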