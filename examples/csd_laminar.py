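"""Current-source-density analysis of laminar LFP sweeps.

The generator inverts the CSD operator (double cumulative summation of a
known sink/source profile), so the analysis should recover a sink at
channel 8 flanked by sources, with amplitude growing with stimulation
intensity.
"""

import numpy as np

from attnephys import csd, synth

sweeps, truth = synth.gen_laminar(
    sink_channel=8, source_channels=(6, 10), noise_sd=1e-6, seed=0
)
m = csd.compute_csd(sweeps.sweeps[0], sweeps.spacing_um, fs=sweeps.fs)
row, col = np.unravel_index(np.argmin(m.values), m.values.shape)
print(f"largest sink at probe channel {row + 2} ({m.channel_depths_um[row]:.0f} um)")

win = csd.ComponentWindow("L23_sink", 7, 9, 0.02, 0.04, "sink")
curve = csd.amplitude_curve(sweeps, win)
print("peak amplitude vs stimulation intensity (V/mm^2, sinks negative):")
for intensity, amp in curve.items():
    print(f"  {intensity:5.0f} uA  {amp:8.3f}")
print(
    "The sink amplitude scales with the injected per-intensity gain; "
    "sources appear as positive flanks at channels 6 and 10."
)
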