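"""Intracellular metrics: 40 Hz IPSP failure rate and spike reduction.

Simulates optogenetic IPSP trains with 70% release probability (so ~30%
failures are expected) and noisy-current-driven spiking with 50%
inhibition, then runs the failure and spike-reduction analyses.
"""

from attnephys import intracellular, synth

sweeps = synth.gen_ipsp_sweeps(n_trials=5, p_release=0.7, noise_sd_mv=0.03, seed=1)
report = intracellular.ipsp_failures(sweeps)
print(f"per-sweep failure %: {report.per_sweep_pct}")
print(f"per-cell mean failure rate: {report.per_cell_mean_pct:.1f}% "
      f"(expected ~30% at p_release = 0.7)")

current = synth.gen_noisy_current(seed=2)
spike_sweeps = synth.gen_spike_sweeps(current, inhibition_fraction=0.5, n_trials=5, seed=2)
counts = {
    cond: [intracellular.detect_spikes(s.vm).size for s in spike_sweeps if s.condition == cond]
    for cond in ("no_light", "train_40hz")
}
red = intracellular.spike_reduction(counts["no_light"], counts["train_40hz"])
print(f"spikes no-light {counts['no_light']} vs 40 Hz light {counts['train_40hz']}")
print(f"spike reduction: {red['pct']:.1f}% (expected ~50%)")
print(
    "A failure is a pulse-locked deflection below 0.25 mV in the 25 ms "
    "post-TTL window; reduction uses the no-light count as denominator."
)
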