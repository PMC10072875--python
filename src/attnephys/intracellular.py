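"""Intracellular (current-clamp) metrics.

Covers threshold-based spike detection, the spike-reduction rate under
optogenetic inhibition, membrane/spiking metrics restricted to the last
0.5 s analysis bin of a light step, and synaptic failure analysis of
40 Hz IPSP trains (a response smaller than 0.25 mV within the 25 ms
post-pulse window counts as a failure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .signals import ContinuousSignal, IntracellularSweep

FAILURE_THRESHOLD_MV = 0.25
RESPONSE_WINDOW_S = 0.025


@dataclass
class PulseResponse:
    pulse_index: int
    peak_deflection_mv: float  # signed; negative = hyperpolarizing
    is_failure: bool


@dataclass
class FailureReport:
    """Per-sweep failure percentages and their per-cell mean."""

    per_sweep_pct: list[float]
    per_cell_mean_pct: float
    n_pulses: int
    responses: list[list[PulseResponse]] = field(default_factory=list)


@dataclass
class SpikeTrainMetrics:
    spike_count_last_bin: int
    mean_vm_last_bin_mv: float
    mean_vm_baseline_mv: float
    window_flagged: bool = False


def detect_spikes(
    vm: ContinuousSignal, threshold_mv: float = 0.0, refractory_s: float = 0.002
) -> np.ndarray:
    """Spike times from upward threshold crossings, one per refractory window."""
    x = vm.samples
    above = x > threshold_mv
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if crossings.size == 0:
        if above.size and above[0]:
            crossings = np.array([0])
        else:
            return np.empty(0)
    elif above[0]:
        crossings = np.concatenate(([0], crossings))
    refr_n = int(round(refractory_s * vm.fs))
    kept = [int(crossings[0])]
    for c in crossings[1:]:
        if c - kept[-1] > refr_n:
            kept.append(int(c))
    return vm.t0 + np.asarray(kept) / vm.fs


def spike_reduction(
    no_light_counts: np.ndarray, light_counts: np.ndarray
) -> dict[str, float]:
    """Percent spike reduction under light.

    Primary definition: 100 * (mean_nolight - mean_light) / mean_nolight,
    bounded by 100% for complete silencing.  The alternative reading of the
    reduction formula (light-count denominator) is emitted alongside as
    ``pct_light_denominator``; it is unbounded and NaN when the light count
    is zero.
    """
    nl = float(np.mean(no_light_counts))
    li = float(np.mean(light_counts))
    if nl <= 0:
        raise ValueError("spike reduction undefined: no spikes in no-light sweeps")
    alt = 100.0 * (nl - li) / li if li > 0 else float("nan")
    return {
        "pct": 100.0 * (nl - li) / nl,
        "pct_light_denominator": alt,
        "mean_no_light": nl,
        "mean_light": li,
    }


def last_bin_metrics(
    sweep: IntracellularSweep,
    light_on_s: float,
    light_len_s: float,
    bin_s: float = 0.5,
    spike_threshold_mv: float = 0.0,
    refractory_s: float = 0.002,
) -> SpikeTrainMetrics:
    """Spike count and mean Vm over the last 0.5 s of the light window,
    with baseline Vm over the 0.5 s immediately before light onset."""
    vm = sweep.vm
    end = light_on_s + light_len_s
    if light_on_s - bin_s < vm.t0 or end > vm.t0 + vm.duration_s + 1e-9:
        raise ValueError("light interval (plus baseline) must lie within the sweep")
    flagged = False
    if light_len_s < bin_s:
        warnings.warn(
            "light window shorter than the analysis bin; using the full window",
            stacklevel=2,
        )
        bin_s = light_len_s
        flagged = True
    i_last0 = vm.index_at(end - bin_s)
    i_last1 = vm.index_at(end)
    i_base0 = vm.index_at(light_on_s - 0.5)
    i_base1 = vm.index_at(light_on_s)
    spikes = detect_spikes(vm, spike_threshold_mv, refractory_s)
    n_last = int(np.sum((spikes >= end - bin_s) & (spikes < end)))
    return SpikeTrainMetrics(
        spike_count_last_bin=n_last,
        mean_vm_last_bin_mv=float(vm.samples[i_last0:i_last1].mean()),
        mean_vm_baseline_mv=float(vm.samples[max(i_base0, 0):i_base1].mean()),
        window_flagged=flagged,
    )


def _pulse_responses(
    sweep: IntracellularSweep,
    failure_threshold_mv: float,
    window_s: float,
    baseline_s: float,
) -> list[PulseResponse]:
    vm = sweep.vm
    ttls = np.sort(sweep.light_ttl_times_s)
    if ttls.size == 0:
        raise ValueError("sweep has no TTL pulses")
    if ttls.size > 1 and np.any(np.diff(ttls) < window_s - 1e-12):
        raise ValueError("TTL spacing shorter than the response window")
    out = []
    for k, ttl in enumerate(ttls):
        i_ttl = vm.index_at(ttl)
        i_base = vm.index_at(ttl - baseline_s)
        i_end = vm.index_at(ttl + window_s)
        baseline = float(vm.samples[max(i_base, 0):i_ttl].mean())
        seg = vm.samples[i_ttl:i_end] - baseline
        peak = float(seg[np.argmax(np.abs(seg))])  # signed extremum
        out.append(
            PulseResponse(
                pulse_index=k,
                peak_deflection_mv=peak,
                is_failure=abs(peak) < failure_threshold_mv,
            )
        )
    return out


def ipsp_failures(
    sweeps: IntracellularSweep | list[IntracellularSweep],
    failure_threshold_mv: float = FAILURE_THRESHOLD_MV,
    window_s: float = RESPONSE_WINDOW_S,
    baseline_s: float = 0.002,
) -> FailureReport:
    """Failure analysis of 40 Hz IPSP trains.

    Each response is aligned to its TTL pulse; baseline is the mean Vm over
    the 2 ms immediately before the pulse; the peak deflection is the
    absolute extremum of Vm - baseline within the 25 ms post-pulse window
    (half-open, so 40 Hz pulses abut exactly).  |deflection| < 0.25 mV is a
    failure.  Per-sweep failure percentages are averaged into the per-cell
    mean (the paper-style 5-trial average).
    """
    if isinstance(sweeps, IntracellularSweep):
        sweeps = [sweeps]
    per_sweep = []
    all_responses = []
    n_pulses = None
    for sw in sweeps:
        responses = _pulse_responses(sw, failure_threshold_mv, window_s, baseline_s)
        if n_pulses is None:
            n_pulses = len(responses)
        pct = 100.0 * sum(r.is_failure for r in responses) / len(responses)
        per_sweep.append(pct)
        all_responses.append(responses)
    return FailureReport(
        per_sweep_pct=per_sweep,
        per_cell_mean_pct=float(np.mean(per_sweep)),
        n_pulses=n_pulses or 0,
        responses=all_responses,
    )
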