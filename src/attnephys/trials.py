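"""Behavioral trial records and the session trial-table CSV.

A trial in the attentional engagement task (AET) or the variable
delay-to-signal task (VDST): the animal nose-pokes a center port to
initiate, a light cue of varying length indicates the rewarded side,
and the animal chooses the left or right port (or omits).  Sessions
run until 80 minutes have elapsed or 100 trials are complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

TASKS = ("AET", "VDST")
PORTS = ("L", "R")
OUTCOMES = ("correct", "incorrect", "omission")

SESSION_MAX_TRIALS = 100
SESSION_MAX_DURATION_S = 4800.0  # 80 min

_CSV_COLUMNS = [
    "index",
    "task",
    "cue_length_s",
    "delay_s",
    "correct_port",
    "chosen_port",
    "init_time_s",
    "cue_on_s",
    "cue_off_s",
    "choice_time_s",
    "outcome",
]


@dataclass
class TrialRecord:
    index: int
    task: str
    cue_length_s: float
    correct_port: str
    chosen_port: str  # "L", "R" or "none"
    outcome: str
    delay_s: float = 0.0
    init_time_s: float | None = None
    cue_on_s: float | None = None
    cue_off_s: float | None = None
    choice_time_s: float | None = None

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("trial index must be >= 0")
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if not self.cue_length_s > 0:
            raise ValueError("cue_length_s must be > 0")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        if self.correct_port not in PORTS:
            raise ValueError(f"correct_port must be one of {PORTS}")
        if self.chosen_port not in PORTS + ("none",):
            raise ValueError("chosen_port must be 'L', 'R' or 'none'")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        problems = self.consistency_problems()
        if problems:
            raise ValueError(f"inconsistent trial {self.index}: {'; '.join(problems)}")

    def consistency_problems(self) -> list[str]:
        """Internal-consistency violations (empty list when clean)."""
        msgs = []
        if (self.outcome == "omission") != (self.chosen_port == "none"):
            msgs.append("outcome is omission iff chosen_port is none")
        if self.chosen_port in PORTS:
            expected = "correct" if self.chosen_port == self.correct_port else "incorrect"
            if self.outcome != expected:
                msgs.append(
                    f"outcome {self.outcome!r} conflicts with chosen={self.chosen_port} "
                    f"vs correct={self.correct_port}"
                )
        if self.cue_on_s is not None and self.cue_off_s is not None:
            if not math.isclose(
                self.cue_off_s, self.cue_on_s + self.cue_length_s, abs_tol=1e-9
            ):
                msgs.append("cue_off_s must equal cue_on_s + cue_length_s")
        if (
            self.choice_time_s is not None
            and self.cue_on_s is not None
            and self.choice_time_s < self.cue_on_s
        ):
            msgs.append("choice_time_s precedes cue_on_s")
        return msgs

    @property
    def responded(self) -> bool:
        return self.chosen_port != "none"


@dataclass
class SessionTable:
    """Ordered trials of one behavioral session plus metadata."""

    trials: list[TrialRecord]
    session_duration_s: float
    animal_id: str = ""
    genotype: str = ""
    day: str = ""

    def __post_init__(self) -> None:
        if not self.session_duration_s > 0:
            raise ValueError("session_duration_s must be > 0")
        # Sessions end at 100 trials or 80 min, whichever comes first.
        if (
            len(self.trials) > SESSION_MAX_TRIALS
            and self.session_duration_s > SESSION_MAX_DURATION_S
        ):
            raise ValueError(
                f"{len(self.trials)} trials over {self.session_duration_s:.0f} s "
                f"violates the 100-trial / 80-min session cap"
            )
        inits = [t.init_time_s for t in self.trials if t.init_time_s is not None]
        if any(b <= a for a, b in zip(inits, inits[1:])):
            raise ValueError("trial init times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_initiated(self) -> int:
        return len(self.trials)

    def cue_lengths(self) -> list[float]:
        return sorted({t.cue_length_s for t in self.trials})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append(
                {
                    "index": t.index,
                    "task": t.task,
                    "cue_length_s": t.cue_length_s,
                    "delay_s": t.delay_s,
                    "correct_port": t.correct_port,
                    "chosen_port": t.chosen_port,
                    "init_time_s": t.init_time_s,
                    "cue_on_s": t.cue_on_s,
                    "cue_off_s": t.cue_off_s,
                    "choice_time_s": t.choice_time_s,
                    "outcome": t.outcome,
                }
            )
        return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_trial_csv(session: SessionTable, path) -> None:
    """Write a session to CSV (comma, '.' decimal, UTF-8, header row).

    Session metadata travels in ``#``-prefixed header comment lines so the
    CSV stays a single self-contained file.
    """
    frame = session.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# session_duration_s={session.session_duration_s!r}\n")
        fh.write(f"# animal_id={session.animal_id}\n")
        fh.write(f"# genotype={session.genotype}\n")
        fh.write(f"# day={session.day}\n")
        frame.to_csv(fh, index=False)


def read_trial_csv(path) -> SessionTable:
    """Read a trial-table CSV back into a :class:`SessionTable`.

    The outcome column is re-validated against chosen vs correct port and
    the omission rule; inconsistent rows raise with their indices listed.
    """
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"trial CSV missing required columns: {missing}")

    trials: list[TrialRecord] = []
    bad: list[tuple[int, str]] = []
    for _, row in frame.iterrows():
        def opt(name: str) -> float | None:
            v = row[name]
            return None if pd.isna(v) else float(v)

        try:
            trials.append(
                TrialRecord(
                    index=int(row["index"]),
                    task=str(row["task"]),
                    cue_length_s=float(row["cue_length_s"]),
                    delay_s=float(row["delay_s"]),
                    correct_port=str(row["correct_port"]),
                    chosen_port=str(row["chosen_port"]),
                    init_time_s=opt("init_time_s"),
                    cue_on_s=opt("cue_on_s"),
                    cue_off_s=opt("cue_off_s"),
                    choice_time_s=opt("choice_time_s"),
                    outcome=str(row["outcome"]),
                )
            )
        except ValueError as exc:
            bad.append((int(row["index"]), str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise ValueError(f"inconsistent trial rows: {detail}")

    duration = float(meta.get("session_duration_s", SESSION_MAX_DURATION_S))
    return SessionTable(
        trials=trials,
        session_duration_s=duration,
        animal_id=meta.get("animal_id", ""),
        genotype=meta.get("genotype", ""),
        day=meta.get("day", ""),
    )
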