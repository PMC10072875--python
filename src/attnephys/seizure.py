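"""Spike-and-wave discharge (SWD) detection and session-level summaries.

Absence-type SWDs in this mouse model ride at a 7-10 Hz fundamental with a
strong 2nd harmonic.  Detection thresholds the 7-10 Hz band power of the
CWT spectrogram at an adaptive level (median + k*MAD, so the detector is
invariant to overall amplitude scaling), merges brief gaps, keeps events
between 2 and 30 s, and discards candidates whose spectral peak lies
outside the 7-10 Hz band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation

from .spectral import BandDefinition, Spectrogram, band_power
from .trials import SessionTable


@dataclass
class SeizureEvent:
    start_s: float
    end_s: float
    peak_freq_hz: float
    peak_power: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SeizureSummary:
    events: list[SeizureEvent]
    seizures_per_min: float
    pct_trials_with_seizure_within_margin: float
    pct_trials_with_seizure_during_cue: float


def _intervals_from_mask(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index runs where mask is True."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts, ends))


def detect_seizures(
    spec: Spectrogram,
    threshold_k: float = 6.0,
    min_dur_s: float = 2.0,
    max_dur_s: float = 30.0,
    band: tuple[float, float] = (7.0, 10.0),
    merge_gap_s: float = 0.5,
) -> list[SeizureEvent]:
    """Detect SWDs on a raw-power spectrogram.

    Candidates are intervals where 7-10 Hz band power exceeds
    median + ``threshold_k`` * MAD of that band's power; gaps shorter than
    ``merge_gap_s`` are merged; only durations within [``min_dur_s``,
    ``max_dur_s``] survive; candidates whose (1/f-whitened) spectral argmax
    lies outside the band are discarded.  Events are sorted and
    non-overlapping, and always satisfy the duration and peak-frequency
    rules.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be > 0")
    if spec.params.get("normalized", "none") != "none":
        raise ValueError("detect_seizures expects a raw-power spectrogram")
    lo, hi = band
    if spec.freqs_hz.min() > lo or spec.freqs_hz.max() < hi:
        raise ValueError("spectrogram does not cover the detection band")

    bp = band_power(spec, BandDefinition("detect", lo, hi)).samples
    med = np.median(bp)
    mad = median_abs_deviation(bp)
    if mad == 0:
        mad = np.finfo(float).tiny
    mask = bp > med + threshold_k * mad

    dt = spec.dt
    runs = _intervals_from_mask(mask)
    # merge gaps shorter than merge_gap_s (avoids fragmenting waxing-waning SWDs)
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) * dt < merge_gap_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    # whitened power for peak-frequency attribution: each frequency row
    # divided by its own temporal median, else the 1/f background always
    # puts the argmax at the lowest grid frequency
    row_med = np.median(spec.power, axis=1, keepdims=True)
    row_med[row_med <= 0] = np.finfo(float).tiny

    events: list[SeizureEvent] = []
    for s, e in merged:
        dur = (e - s) * dt
        if not (min_dur_s <= dur <= max_dur_s):
            continue
        mean_white = (spec.power[:, s:e] / row_med).mean(axis=1)
        peak_idx = int(np.argmax(mean_white))
        peak_freq = float(spec.freqs_hz[peak_idx])
        if not (lo <= peak_freq <= hi):
            continue
        events.append(
            SeizureEvent(
                start_s=float(spec.times_s[s]),
                end_s=float(spec.times_s[min(e, spec.times_s.size - 1)]),
                peak_freq_hz=peak_freq,
                peak_power=float(spec.power[peak_idx, s:e].max()),
            )
        )
    for ev in events:  # hard contract on anything we return
        assert min_dur_s <= ev.duration_s <= max_dur_s + dt
        assert lo <= ev.peak_freq_hz <= hi
    return events


def seizure_rate(events: list[SeizureEvent], session_duration_s: float) -> float:
    """Seizure count normalized to session length, in events per minute."""
    if session_duration_s <= 0:
        raise ValueError("session_duration_s must be > 0")
    return len(events) / (session_duration_s / 60.0)


def _intersects(a0: float, a1: float, b0: float, b1: float) -> bool:
    return a0 < b1 and b0 < a1


def trial_overlap(
    events: list[SeizureEvent],
    session: SessionTable,
    margin_s: float = 10.0,
    anchor: str = "trial",
) -> SeizureSummary:
    """Percentage of trials with a seizure near the trial and during the cue.

    A trial counts "within margin" when any event intersects
    [anchor_start - margin, anchor_end + margin]; with ``anchor='trial'``
    the anchor spans initiation to choice (or cue offset for omissions),
    with ``anchor='cue'`` it spans the cue.  "During cue" means any event
    intersects [cue_on, cue_off).  Percentages are over all initiated
    trials.
    """
    if anchor not in ("trial", "cue"):
        raise ValueError("anchor must be 'trial' or 'cue'")
    n = len(session)
    n_margin = 0
    n_cue = 0
    for t in session.trials:
        cue_on = t.cue_on_s if t.cue_on_s is not None else t.init_time_s
        cue_off = t.cue_off_s if t.cue_off_s is not None else cue_on
        if anchor == "trial":
            a0 = t.init_time_s if t.init_time_s is not None else cue_on
            a1 = t.choice_time_s if t.choice_time_s is not None else cue_off
        else:
            a0, a1 = cue_on, cue_off
        hit_margin = any(
            _intersects(ev.start_s, ev.end_s, a0 - margin_s, a1 + margin_s)
            for ev in events
        )
        hit_cue = any(
            _intersects(ev.start_s, ev.end_s, cue_on, cue_off) for ev in events
        )
        n_margin += hit_margin
        n_cue += hit_cue
    rate = seizure_rate(events, session.session_duration_s)
    return SeizureSummary(
        events=events,
        seizures_per_min=rate,
        pct_trials_with_seizure_within_margin=100.0 * n_margin / n if n else 0.0,
        pct_trials_with_seizure_during_cue=100.0 * n_cue / n if n else 0.0,
    )
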