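"""Score a synthetic attentional-engagement-task session.

Accuracy falls with cue length per the injected psychometric curve;
omissions, reaction times, repetitive responding and engagement are
reported alongside.
"""

from attnephys import behavior, synth

psycho = synth.PsychometricParams(
    p_correct={5.0: 0.9, 2.0: 0.7, 0.5: 0.55},
    p_omission={5.0: 0.02, 2.0: 0.05, 0.5: 0.15},
)
session = synth.gen_session(90, cue_lengths=(5.0, 2.0, 0.5), psycho=psycho, seed=8)
summary = behavior.summarize(session)
print(summary.per_cue.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
print(f"repetitive score: {summary.repetitive_score:.3f}   engaged: {summary.engaged}")
print(
    "Accuracy (omissions excluded) tracks the injected psychometric "
    "probabilities; incorrect-trial reaction times run slower by design."
)

print("training criterion day for [75, 72, 71]:", behavior.training_criterion([75, 72, 71]))
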