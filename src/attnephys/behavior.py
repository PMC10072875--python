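"""Operant attention-task scoring.

Accuracy per cue length (omissions excluded from the denominator; they are
reported separately), the 5-s omission rule, reaction times under both the
cue-offset and initiation anchors, the repetitive-responding score (blocks
of five consecutive same-port choices), the training criterion (70% x 3
days or 90% x 2 days) and the 1-trial-per-minute engagement filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .trials import SessionTable, TrialRecord


@dataclass
class BehaviorSummary:
    per_cue: pd.DataFrame      # cue_length_s, pct_correct, pct_omission, RTs, n
    repetitive_score: float
    n_trials: int
    engaged: bool


def score_accuracy(session: SessionTable) -> dict[float, float]:
    """Percent correct per cue length over responded trials.

    accuracy = correct / (correct + incorrect) * 100; omissions are
    excluded; cue lengths with no responded trials are absent from the
    result.
    """
    out: dict[float, float] = {}
    for cue in session.cue_lengths():
        n_c = sum(
            1 for t in session.trials if t.cue_length_s == cue and t.outcome == "correct"
        )
        n_i = sum(
            1 for t in session.trials if t.cue_length_s == cue and t.outcome == "incorrect"
        )
        if n_c + n_i > 0:
            out[cue] = 100.0 * n_c / (n_c + n_i)
    return out


def omission_rates(session: SessionTable) -> dict[float, float]:
    """Percent omissions per cue length over all initiated trials."""
    out: dict[float, float] = {}
    for cue in session.cue_lengths():
        trials = [t for t in session.trials if t.cue_length_s == cue]
        out[cue] = 100.0 * sum(t.outcome == "omission" for t in trials) / len(trials)
    return out


def classify_omissions(session: SessionTable, limit_s: float = 5.0) -> SessionTable:
    """Re-apply the omission rule: no choice, or a choice made more than
    ``limit_s`` after cue termination, is an omission."""
    new_trials: list[TrialRecord] = []
    for t in session.trials:
        late = (
            t.choice_time_s is not None
            and t.cue_off_s is not None
            and t.choice_time_s - t.cue_off_s > limit_s
        )
        if t.chosen_port == "none" or late:
            t = dc_replace(t, chosen_port="none", outcome="omission", choice_time_s=None)
        else:
            outcome = "correct" if t.chosen_port == t.correct_port else "incorrect"
            t = dc_replace(t, outcome=outcome)
        new_trials.append(t)
    return dc_replace(session, trials=new_trials)


def reaction_times(session: SessionTable, anchor: str = "cue_off") -> pd.DataFrame:
    """Per-trial reaction time, split by accuracy.

    ``anchor='cue_off'``: seconds between cue termination and port
    selection; ``anchor='init'``: time from trial initiation to the
    response.  Omissions are excluded; trials with negative RT are flagged
    and excluded.
    """
    if anchor not in ("cue_off", "init"):
        raise ValueError("anchor must be 'cue_off' or 'init'")
    rows = []
    flagged = 0
    for t in session.trials:
        if not t.responded or t.choice_time_s is None:
            continue
        ref = t.cue_off_s if anchor == "cue_off" else t.init_time_s
        if ref is None:
            continue
        rt = t.choice_time_s - ref
        if rt < 0:
            flagged += 1
            continue
        rows.append({"trial": t.index, "cue_length_s": t.cue_length_s,
                     "outcome": t.outcome, "rt_s": rt})
    if flagged:
        warnings.warn(f"reaction_times: excluded {flagged} trial(s) with negative RT",
                      stacklevel=2)
    return pd.DataFrame(rows, columns=["trial", "cue_length_s", "outcome", "rt_s"])


def repetitive_score(
    session: SessionTable, block: int = 5, sliding: bool = False
) -> float:
    """Repetitive-responding score.

    Scans the responded-choice sequence; each maximal run of identical port
    choices of length L contributes floor(L/5) disjoint five-trial blocks
    (or L-4 overlapping windows with ``sliding=True``), normalized by the
    number of responded trials.
    """
    choices = [t.chosen_port for t in session.trials if t.responded]
    if len(choices) < block:
        warnings.warn("repetitive_score: fewer than 5 responded trials; score 0",
                      stacklevel=2)
        return 0.0
    runs = []
    run_len = 1
    for prev, cur in zip(choices, choices[1:]):
        if cur == prev:
            run_len += 1
        else:
            runs.append(run_len)
            run_len = 1
    runs.append(run_len)
    if sliding:
        n_blocks = sum(max(0, r - block + 1) for r in runs)
    else:
        n_blocks = sum(r // block for r in runs)
    return n_blocks / len(choices)


def training_criterion(daily_accuracy: list[float]) -> int | None:
    """First (1-based) day the training criterion is met, else None.

    Criterion: >= 70% correct on 3 consecutive days, or >= 90% on 2
    consecutive days.
    """
    acc = list(daily_accuracy)
    if any(not 0 <= a <= 100 for a in acc):
        raise ValueError("accuracies must be percentages in [0, 100]")
    for d in range(len(acc)):
        if d >= 2 and all(a >= 70 for a in acc[d - 2 : d + 1]):
            return d + 1
        if d >= 1 and all(a >= 90 for a in acc[d - 1 : d + 1]):
            return d + 1
    return None


def engagement_filter(session: SessionTable, rate_per_min: float = 1.0) -> bool:
    """Engaged iff initiated trials per minute >= the rate (default 1/min)."""
    minutes = session.session_duration_s / 60.0
    return len(session) / minutes >= rate_per_min


def summarize(session: SessionTable, block: int = 5) -> BehaviorSummary:
    """Full per-session behavioral summary table."""
    acc = score_accuracy(session)
    omit = omission_rates(session)
    rts = reaction_times(session)
    rows = []
    for cue in session.cue_lengths():
        sub = rts[rts.cue_length_s == cue]
        rows.append(
            {
                "cue_length_s": cue,
                "pct_correct": acc.get(cue, np.nan),
                "pct_omission": omit[cue],
                "rt_correct_s": sub[sub.outcome == "correct"].rt_s.mean(),
                "rt_incorrect_s": sub[sub.outcome == "incorrect"].rt_s.mean(),
                "n_trials": sum(t.cue_length_s == cue for t in session.trials),
            }
        )
    return BehaviorSummary(
        per_cue=pd.DataFrame(rows),
        repetitive_score=repetitive_score(session, block=block),
        n_trials=len(session),
        engaged=engagement_filter(session),
    )
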