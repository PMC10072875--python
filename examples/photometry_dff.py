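"""Fiber-photometry processing: motion correction, dF/F, trial features.

Builds a behavioral session with cue-locked calcium transients of known
amplitude (larger on correct trials), adds shared motion artifact, and
recovers per-trial peak, average and time-to-peak from the dF/F.
"""

import numpy as np

from attnephys import photometry, synth

session = synth.gen_session(40, psycho=synth.PsychometricParams(p_omission=0.0), seed=3)
amps = np.array([0.06 if t.outcome == "correct" else 0.02 for t in session.trials])
truth = synth.TransientGroundTruth(amplitudes=amps)
rec, _ = synth.gen_photometry(session, truth, motion_scale=1.0, noise_sd=0.01, seed=4)

dff = photometry.process_recording(rec)  # isosbestic regression + median dF/F
a, b, resid = dff.fit
print(f"isosbestic fit: 470 ~= {a:.2f} * 405 + {b:.1f} (residual RMS {resid:.3f})")

aligned = photometry.segment_trials(dff, session)
feats = photometry.trial_features(aligned)
for outcome, group in feats.groupby("outcome"):
    print(
        f"{outcome:9s}  n={len(group):2d}  peak dF/F {group.peak_amplitude.mean():.4f}"
        f"  cue mean {group.cue_mean.mean():.4f}  time-to-peak {group.time_to_peak_s.mean():.2f} s"
    )
print(
    "Peak amplitudes track the injected 0.06 (correct) vs 0.02 (incorrect) "
    "transients; the baseline window is the 1 s before cue onset."
)
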