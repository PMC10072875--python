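"""Run configuration: named parameter groups for every analysis stage.

Parameters are validated against their documented ranges at load time so a
bad config fails before any computation starts.  YAML round-trips exactly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid config: {msg}")


@dataclass
class SpectralConfig:
    omega0: float = 6.0          # Morlet center frequency (rad)
    freq_min_hz: float = 1.0
    freq_max_hz: float = 100.0
    n_voices: int = 48           # log-spaced frequency grid size
    target_fs_hz: float = 1000.0 # decimate ECoG to this rate before CWT
    peak_normalize_per_freq: bool = False

    def validate(self) -> None:
        _check(self.omega0 > 0, "omega0 must be > 0")
        _check(0 < self.freq_min_hz < self.freq_max_hz, "frequency grid inverted")
        _check(self.n_voices >= 4, "need at least 4 voices")
        _check(self.target_fs_hz >= 2 * self.freq_max_hz, "target fs below Nyquist")


@dataclass
class SeizureConfig:
    threshold_k: float = 6.0     # median + k*MAD on 7-10 Hz band power
    min_dur_s: float = 2.0
    max_dur_s: float = 30.0
    band_lo_hz: float = 7.0
    band_hi_hz: float = 10.0
    merge_gap_s: float = 0.5
    overlap_margin_s: float = 10.0
    margin_anchor: str = "trial"  # "trial" or "cue"

    def validate(self) -> None:
        _check(self.threshold_k > 0, "threshold_k must be > 0")
        _check(0 < self.min_dur_s < self.max_dur_s, "duration window inverted")
        _check(0 < self.band_lo_hz < self.band_hi_hz, "seizure band inverted")
        _check(self.merge_gap_s >= 0, "merge_gap_s must be >= 0")
        _check(self.margin_anchor in ("trial", "cue"), "margin_anchor must be trial|cue")


@dataclass
class PhotometryConfig:
    pre_s: float = 1.0           # baseline window before cue onset
    post_s: float = 5.0          # analysis window after cue onset
    sliding_median: bool = False # session-wide median by default

    def validate(self) -> None:
        _check(self.pre_s > 0 and self.post_s > 0, "trial windows must be positive")


@dataclass
class CsdConfig:
    vaknin_pad: bool = False     # keep edge channels via boundary duplication
    # component windows: name -> (ch_lo, ch_hi, t_lo_s, t_hi_s, sign)
    components: dict = field(
        default_factory=lambda: {
            "L23_sink_early": [4, 7, 0.002, 0.010, "sink"],
            "L23_source": [4, 7, 0.010, 0.040, "source"],
            "L23_sink_late": [3, 6, 0.010, 0.040, "sink"],
            "L5_sink": [9, 12, 0.002, 0.010, "sink"],
        }
    )

    def validate(self) -> None:
        for name, (clo, chi, tlo, thi, sign) in self.components.items():
            _check(clo <= chi, f"component {name}: channel range inverted")
            _check(tlo < thi, f"component {name}: latency window inverted")
            _check(sign in ("sink", "source"), f"component {name}: bad sign")


@dataclass
class IntracellularConfig:
    spike_threshold_mv: float = 0.0
    refractory_s: float = 0.002
    failure_threshold_mv: float = 0.25
    response_window_s: float = 0.025
    baseline_window_s: float = 0.002  # pre-TTL baseline for IPSP deflection

    def validate(self) -> None:
        _check(self.refractory_s >= 0, "refractory must be >= 0")
        _check(self.failure_threshold_mv > 0, "failure threshold must be > 0")
        _check(self.response_window_s > 0, "response window must be > 0")
        _check(self.baseline_window_s > 0, "baseline window must be > 0")


@dataclass
class BehaviorConfig:
    omission_limit_s: float = 5.0
    rt_anchor: str = "cue_off"    # "cue_off" (Results defn) or "init" (Methods defn)
    repetitive_block: int = 5
    repetitive_sliding: bool = False
    engagement_rate_per_min: float = 1.0

    def validate(self) -> None:
        _check(self.omission_limit_s > 0, "omission limit must be > 0")
        _check(self.rt_anchor in ("cue_off", "init"), "rt_anchor must be cue_off|init")
        _check(self.repetitive_block >= 2, "repetitive block must be >= 2")
        _check(self.engagement_rate_per_min > 0, "engagement rate must be > 0")


@dataclass
class DecodingConfig:
    outlier_factor: float = 10.0
    smote_k_neighbors: int = 5
    cv_folds: int = 10
    cv_repeats: int = 3
    row_subsample: float = 0.8
    col_subsample: float = 0.3
    max_depth: int = 3
    n_rounds: int = 200
    learning_rate: float = 0.1
    rebalance_in_folds: bool = True  # leakage-safe; False = resample before CV

    def validate(self) -> None:
        _check(self.outlier_factor > 0, "outlier_factor must be > 0")
        _check(self.smote_k_neighbors >= 1, "smote_k_neighbors must be >= 1")
        _check(self.cv_folds >= 2, "cv_folds must be >= 2")
        _check(self.cv_repeats >= 1, "cv_repeats must be >= 1")
        _check(0 < self.row_subsample <= 1, "row_subsample in (0, 1]")
        _check(0 < self.col_subsample <= 1, "col_subsample in (0, 1]")
        _check(self.max_depth >= 1 and self.n_rounds >= 1, "tree params must be >= 1")
        _check(self.learning_rate > 0, "learning_rate must be > 0")


@dataclass
class SynthConfig:
    ecog_fs_hz: float = 1000.0
    ecog_duration_s: float = 600.0
    swd_rate_per_min: float = 0.3
    swd_amplitude_rms: float = 5.0  # SWD amplitude relative to background RMS
    photometry_fs_hz: float = 20.0
    n_trials: int = 60
    cue_lengths_s: tuple = (5.0, 2.0, 0.5)

    def validate(self) -> None:
        _check(self.ecog_fs_hz >= 200, "ECoG fs must be >= 200 Hz")
        _check(self.ecog_duration_s > 0, "ECoG duration must be > 0")
        _check(self.swd_rate_per_min >= 0, "SWD rate must be >= 0")
        _check(self.swd_amplitude_rms > 0, "SWD amplitude scale must be > 0")
        _check(1 <= self.n_trials <= 100, "n_trials in [1, 100]")
        _check(len(self.cue_lengths_s) > 0, "need at least one cue length")


@dataclass
class AnalysisConfig:
    seed: int = 0
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    seizure: SeizureConfig = field(default_factory=SeizureConfig)
    photometry: PhotometryConfig = field(default_factory=PhotometryConfig)
    csd: CsdConfig = field(default_factory=CsdConfig)
    intracellular: IntracellularConfig = field(default_factory=IntracellularConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def validate(self) -> "AnalysisConfig":
        _check(0 <= self.seed < 2**31, "seed must be in [0, 2^31)")
        for f in fields(self):
            group = getattr(self, f.name)
            if hasattr(group, "validate"):
                group.validate()
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        groups = {}
        for f in fields(cls):
            if f.name == "seed":
                continue
            sub = data.get(f.name, {})
            typ = f.default_factory  # the group dataclass
            known = {g.name for g in fields(typ)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown keys in config group {f.name}: {sorted(unknown)}")
            if f.name == "synth" and "cue_lengths_s" in sub:
                sub = dict(sub, cue_lengths_s=tuple(sub["cue_lengths_s"]))
            groups[f.name] = typ(**sub)
        cfg = cls(seed=int(data.get("seed", 0)), **groups)
        return cfg.validate()

    def save_yaml(self, path: str | Path) -> None:
        data = self.to_dict()
        data["synth"]["cue_lengths_s"] = list(data["synth"]["cue_lengths_s"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def load_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
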