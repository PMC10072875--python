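"""Current-source-density analysis of laminar LFP sweeps.

CSD is the negated second spatial difference of the LFP across the
16-channel probe (100 um spacing): net inward membrane current (a sink)
creates an extracellular negativity and a negative CSD deflection, sources
are positive.  Units are V/mm^2 (tissue conductivity is deliberately
omitted).  Edge channels are dropped unless Vaknin-style boundary
duplication is requested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signals import LaminarSweepSet


@dataclass
class CSDMap:
    values: np.ndarray           # (n_channels - 2, n_times), V/mm^2; sinks < 0
    channel_depths_um: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.values.shape[0] != self.channel_depths_um.size:
            raise ValueError("one depth per CSD row required")


@dataclass
class ComponentWindow:
    """A named sink/source component: interior-channel range x latency window.

    Channels are 1-based probe channels (interior only); the latency window
    is in seconds relative to sweep start; ``sign`` says whether the
    component extremum is a sink (minimum) or source (maximum).
    """

    name: str
    ch_lo: int
    ch_hi: int
    t_lo_s: float
    t_hi_s: float
    sign: str  # "sink" | "source"

    def __post_init__(self) -> None:
        if self.sign not in ("sink", "source"):
            raise ValueError("sign must be 'sink' or 'source'")
        if self.ch_lo > self.ch_hi or self.t_lo_s >= self.t_hi_s:
            raise ValueError(f"component {self.name}: empty window")


def compute_csd(
    sweep: np.ndarray,
    spacing_um: float = 100.0,
    fs: float = 1.0,
    vaknin_pad: bool = False,
) -> CSDMap:
    """CSD_i(t) = -(V_{i-1} - 2 V_i + V_{i+1}) / h^2 for interior channels.

    ``sweep`` is (n_channels, n_times) in volts, ``spacing_um`` the
    inter-electrode spacing (h, converted to mm).  With ``vaknin_pad`` the
    edge channels are retained by duplicating the boundary LFP rows.
    """
    sweep = np.asarray(sweep, float)
    if sweep.ndim != 2 or sweep.shape[0] < 3:
        raise ValueError("need a (channels >= 3) x time LFP matrix")
    if spacing_um <= 0:
        raise ValueError("spacing must be > 0")
    v = np.vstack([sweep[:1], sweep, sweep[-1:]]) if vaknin_pad else sweep
    h_mm = spacing_um / 1000.0
    csd = -(v[:-2] - 2 * v[1:-1] + v[2:]) / h_mm**2
    if vaknin_pad:
        depths = np.arange(sweep.shape[0]) * spacing_um
    else:
        depths = np.arange(1, sweep.shape[0] - 1) * spacing_um
    return CSDMap(values=csd, channel_depths_um=depths, fs=fs)


def trial_average(maps: list[CSDMap]) -> CSDMap:
    """Element-wise mean CSD over sweeps (e.g. the 10 trials per intensity)."""
    if not maps:
        raise ValueError("no maps to average")
    shapes = {m.values.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"mixed CSD shapes: {sorted(shapes)}")
    mean = np.mean([m.values for m in maps], axis=0)
    return CSDMap(values=mean, channel_depths_um=maps[0].channel_depths_um, fs=maps[0].fs)


def component_amplitude(csd_map: CSDMap, win: ComponentWindow, n_channels: int = 16) -> float:
    """Signed peak of a component: minimum for sinks, maximum for sources.

    Channel indices in ``win`` are 1-based probe channels; the map holds
    interior channels 2..n-1.  A "source" window whose extremum comes out
    negative (or a sink's positive) is returned as-is with a warning.
    """
    row_lo = win.ch_lo - 2  # probe channel 2 -> map row 0
    row_hi = win.ch_hi - 2
    if row_lo < 0 or row_hi >= csd_map.values.shape[0]:
        raise ValueError(f"component {win.name}: channel range outside the map")
    i_lo = int(round(win.t_lo_s * csd_map.fs))
    i_hi = int(round(win.t_hi_s * csd_map.fs))
    if i_lo < 0 or i_hi > csd_map.values.shape[1]:
        raise ValueError(f"component {win.name}: latency window outside the map")
    block = csd_map.values[row_lo : row_hi + 1, i_lo:i_hi]
    peak = float(block.min() if win.sign == "sink" else block.max())
    if (win.sign == "source" and peak < 0) or (win.sign == "sink" and peak > 0):
        warnings.warn(
            f"component {win.name}: extremum sign ({peak:+.3g}) disagrees with "
            f"its '{win.sign}' designation",
            stacklevel=2,
        )
    return peak


def amplitude_curve(
    sweeps: LaminarSweepSet, win: ComponentWindow
) -> dict[float, float]:
    """Component peak amplitude vs stimulation intensity (trial-averaged).

    Sweeps are grouped by intensity, CSD-transformed, averaged within each
    intensity, and the component's signed peak extracted — one point per
    intensity, sorted.
    """
    out: dict[float, float] = {}
    for intensity in np.unique(sweeps.stim_intensity_ua):
        group = [
            compute_csd(sw, spacing_um=sweeps.spacing_um, fs=sweeps.fs)
            for sw, amp in zip(sweeps.sweeps, sweeps.stim_intensity_ua)
            if amp == intensity
        ]
        out[float(intensity)] = component_amplitude(trial_average(group), win)
    return dict(sorted(out.items()))
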