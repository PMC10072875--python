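"""Uniformly sampled signal container and its on-disk format.

A :class:`ContinuousSignal` holds one channel of a continuous recording
(ECoG, membrane voltage, a photometry wavelength, an injected current).
Collections of channels are persisted as a flat little-endian float64
binary file plus a JSON metadata sidecar (``<path>.json``) carrying the
format version and per-channel sampling rate, start time, units and byte
layout.  The pairing keeps the data language-neutral, inspectable with a
hex editor, and bit-exact on round trip.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1
_DTYPE = np.dtype("<f8")


@dataclass
class ContinuousSignal:
    """One uniformly sampled 1-D recording channel.

    Parameters
    ----------
    samples
        Sample values.  Volts (or mV where stated) for electrophysiology,
        arbitrary fluorescence units for photometry.
    fs
        Sampling rate in Hz, strictly positive.
    t0
        Time of the first sample in seconds relative to session start.
    label
        Channel name, unique within a container.
    units
        Unit string, e.g. ``"V"``, ``"mV"``, ``"au"``, ``"pA"``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = "signal"
    units: str = "au"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not (self.fs > 0) or not math.isfinite(self.fs):
            raise ValueError(f"sampling rate must be positive and finite, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"channel {self.label!r} contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (t0 + n/fs, 0-based indexing)."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_at(self, t_s: float) -> int:
        """Nearest sample index for a time in seconds."""
        return int(round((t_s - self.t0) * self.fs))


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_signal_container(signals: list[ContinuousSignal], path: str | Path) -> None:
    """Write channels to ``path`` (binary) + ``path.json`` (metadata sidecar).

    Raises ``ValueError`` on duplicate labels; non-finite samples are
    rejected by the :class:`ContinuousSignal` constructor itself.
    """
    path = Path(path)
    labels = [s.label for s in signals]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate channel labels: {dupes}")
    channels = []
    offset = 0
    with open(path, "wb") as fh:
        for s in signals:
            if not np.all(np.isfinite(s.samples)):
                raise ValueError(f"channel {s.label!r} contains non-finite samples")
            raw = np.ascontiguousarray(s.samples, dtype=_DTYPE).tobytes()
            fh.write(raw)
            channels.append(
                {
                    "label": s.label,
                    "fs_hz": s.fs,
                    "t0_s": s.t0,
                    "units": s.units,
                    "n_samples": int(s.samples.size),
                    "byte_offset": offset,
                }
            )
            offset += len(raw)
    meta = {"format_version": FORMAT_VERSION, "dtype": "<f8", "channels": channels}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_signal_container(path: str | Path) -> list[ContinuousSignal]:
    """Inverse of :func:`write_signal_container`; bit-exact."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not path.exists():
        raise FileNotFoundError(f"no data file at {path}")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt metadata sidecar {sidecar}: {exc}") from exc
    for key in ("format_version", "dtype", "channels"):
        if key not in meta:
            raise KeyError(f"metadata sidecar missing required key {key!r}")
    if meta["format_version"] != FORMAT_VERSION:
        raise ValueError(
            f"unknown container format version {meta['format_version']!r} "
            f"(this reader handles version {FORMAT_VERSION})"
        )
    blob = path.read_bytes()
    out: list[ContinuousSignal] = []
    for ch in meta["channels"]:
        for key in ("label", "fs_hz", "t0_s", "units", "n_samples", "byte_offset"):
            if key not in ch:
                raise KeyError(f"channel record missing required key {key!r}")
        start = ch["byte_offset"]
        end = start + ch["n_samples"] * _DTYPE.itemsize
        if end > len(blob):
            raise ValueError(
                f"truncated container: channel {ch['label']!r} needs bytes "
                f"[{start}, {end}) but file has {len(blob)}"
            )
        samples = np.frombuffer(blob[start:end], dtype=_DTYPE).copy()
        out.append(
            ContinuousSignal(
                samples=samples,
                fs=ch["fs_hz"],
                t0=ch["t0_s"],
                label=ch["label"],
                units=ch["units"],
            )
        )
    return out


@dataclass
class PhotometryRecording:
    """Dual-wavelength fiber-photometry session.

    470 nm carries the calcium-dependent GCaMP signal; 405 nm is the
    isosbestic (calcium-independent) motion reference.  Both nominally
    sampled at 20 Hz after de-interleaving the alternating 40 Hz pulses.
    """

    sig470: ContinuousSignal
    ref405: ContinuousSignal
    trial_ttl_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.trial_ttl_times_s = np.asarray(self.trial_ttl_times_s, dtype=np.float64)
        if self.sig470.fs != self.ref405.fs:
            raise ValueError("470 and 405 channels must share a sampling rate")
        if self.sig470.samples.size != self.ref405.samples.size:
            raise ValueError("470 and 405 channels must have equal length")


@dataclass
class LaminarSweepSet:
    """Stimulus-evoked LFP sweeps from a 16-channel laminar probe.

    Each sweep is a (n_channels, n_samples) matrix in volts; channels are
    ordered superficial to deep at ``spacing_um`` inter-electrode spacing.
    """

    sweeps: list[np.ndarray]
    fs: float
    stim_intensity_ua: np.ndarray
    stim_onset_s: float
    n_channels: int = 16
    spacing_um: float = 100.0

    def __post_init__(self) -> None:
        self.stim_intensity_ua = np.asarray(self.stim_intensity_ua, dtype=np.float64)
        shapes = {s.shape for s in self.sweeps}
        if len(shapes) > 1:
            raise ValueError(f"all sweeps must share a shape, got {sorted(shapes)}")
        if self.sweeps and self.sweeps[0].shape[0] != self.n_channels:
            raise ValueError("sweep row count does not match n_channels")
        if len(self.sweeps) != self.stim_intensity_ua.size:
            raise ValueError("one stimulation intensity per sweep required")


@dataclass
class IntracellularSweep:
    """One current-clamp sweep: Vm (mV), optional injected current, TTLs."""

    vm: ContinuousSignal
    stim_current: ContinuousSignal | None = None
    light_ttl_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    condition: str = "no_light"  # no_light | continuous_light | train_40hz

    def __post_init__(self) -> None:
        self.light_ttl_times_s = np.asarray(self.light_ttl_times_s, dtype=np.float64)
        if self.condition not in ("no_light", "continuous_light", "train_40hz"):
            raise ValueError(f"unknown condition {self.condition!r}")
        dur = self.vm.t0 + self.vm.duration_s
        if self.light_ttl_times_s.size and (
            self.light_ttl_times_s.min() < self.vm.t0
            or self.light_ttl_times_s.max() >= dur
        ):
            raise ValueError("TTL times must lie within the sweep")
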