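import numpy as np
import pytest

from attnephys.synth import PsychometricParams, gen_session
from attnephys.trials import SessionTable, TrialRecord


def make_trial(
    index=0,
    cue=2.0,
    correct="L",
    chosen="L",
    init=10.0,
    rt=0.7,
    task="AET",
) -> TrialRecord:
    """Hand-built consistent trial; chosen='none' makes an omission."""
    cue_on = init
    cue_off = cue_on + cue
    if chosen == "none":
        outcome, choice_time = "omission", None
    else:
        outcome = "correct" if chosen == correct else "incorrect"
        choice_time = cue_off + rt
    return TrialRecord(
        index=index,
        task=task,
        cue_length_s=cue,
        correct_port=correct,
        chosen_port=chosen,
        init_time_s=init,
        cue_on_s=cue_on,
        cue_off_s=cue_off,
        choice_time_s=choice_time,
        outcome=outcome,
    )


def make_session(choices, correct=None, cue=2.0, spacing=30.0) -> SessionTable:
    """Session from a choice sequence ('L'/'R'/'none'); correct defaults to 'L'."""
    correct = correct or ["L"] * len(choices)
    trials = [
        make_trial(index=i, cue=cue, correct=c, chosen=ch, init=10.0 + i * spacing)
        for i, (ch, c) in enumerate(zip(choices, correct))
    ]
    return SessionTable(trials=trials, session_duration_s=10.0 + len(choices) * spacing)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_session():
    return gen_session(
        30, cue_lengths=(5.0, 2.0, 0.5), psycho=PsychometricParams(), seed=11
    )
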