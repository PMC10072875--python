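"""End-to-end orchestration: simulate -> analyze -> report, with provenance.

``run_pipeline`` executes the configured stages in dependency order,
writing every stage output (CSV/JSON/signal container) under an output
directory together with a run manifest (config snapshot, per-stage seeds,
SHA-256 hashes of every output).  Identical config + seed produces
byte-identical outputs.  A single global seed is fanned out to per-stage
child seeds through a counter-based SeedSequence scheme, so each stage is
reproducible independent of execution order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, csd, decoding, intracellular, photometry, seizure, spectral, synth
from .config import AnalysisConfig
from .trials import write_trial_csv

_STAGE_IDS = {
    "session": 1, "ecog": 2, "photometry": 3, "decoding": 4,
    "laminar": 5, "ipsp": 6, "spikes": 7,
}


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def stage_seed(global_seed: int, stage: str) -> int:
    ss = np.random.SeedSequence([int(global_seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stage_seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    completed_stages: list = field(default_factory=list)

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def _write_csv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False, float_format="%.12g")


def run_pipeline(config: AnalysisConfig, out_dir: str | Path) -> RunManifest:
    """Run the full synthetic demo pipeline; see the module docstring."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    sc = config.synth

    def run_stage(name: str, fn) -> object:
        try:
            result = fn()
        except Exception as exc:
            manifest.save(out / "manifest.json")
            raise PipelineError(name, exc) from exc
        manifest.completed_stages.append(name)
        return result

    # --- behavior -----------------------------------------------------------
    seed_sess = stage_seed(config.seed, "session")
    manifest.stage_seeds["session"] = seed_sess

    def _session():
        sess = synth.gen_session(
            n_trials=sc.n_trials, cue_lengths=sc.cue_lengths_s, seed=seed_sess
        )
        write_trial_csv(sess, out / "session.csv")
        summary = behavior.summarize(sess, block=config.behavior.repetitive_block)
        _write_csv(out / "behavior_summary.csv", summary.per_cue)
        _write_json(
            out / "behavior.json",
            {
                "repetitive_score": summary.repetitive_score,
                "n_trials": summary.n_trials,
                "engaged": bool(summary.engaged),
            },
        )
        return sess

    session = run_stage("session", _session)

    # --- ECoG + seizures ----------------------------------------------------
    seed_ecog = stage_seed(config.seed, "ecog")
    manifest.stage_seeds["ecog"] = seed_ecog

    def _seizures():
        ecog, truth = synth.gen_ecog(
            duration_s=sc.ecog_duration_s,
            fs=sc.ecog_fs_hz,
            swd_rate_per_min=sc.swd_rate_per_min,
            amplitude_rms=sc.swd_amplitude_rms,
            seed=seed_ecog,
        )
        spec = spectral.morlet_cwt(
            ecog,
            spectral.default_freq_grid(
                config.spectral.freq_min_hz,
                config.spectral.freq_max_hz,
                config.spectral.n_voices,
            ),
            omega0=config.spectral.omega0,
        )
        events = seizure.detect_seizures(
            spec,
            threshold_k=config.seizure.threshold_k,
            min_dur_s=config.seizure.min_dur_s,
            max_dur_s=config.seizure.max_dur_s,
            band=(config.seizure.band_lo_hz, config.seizure.band_hi_hz),
            merge_gap_s=config.seizure.merge_gap_s,
        )
        rate = seizure.seizure_rate(events, ecog.duration_s)
        _write_json(
            out / "seizures.json",
            {
                "events": [
                    {
                        "start_s": e.start_s,
                        "end_s": e.end_s,
                        "peak_freq_hz": e.peak_freq_hz,
                    }
                    for e in events
                ],
                "seizures_per_min": rate,
                "n_true_injected": len(truth),
            },
        )
        return events

    run_stage("seizures", _seizures)

    # --- photometry ---------------------------------------------------------
    seed_phot = stage_seed(config.seed, "photometry")
    manifest.stage_seeds["photometry"] = seed_phot

    def _photometry():
        rng = np.random.default_rng(seed_phot)
        # correct trials carry larger cue-locked transients than incorrect
        amps = np.array(
            [
                (0.05 if t.outcome == "correct" else 0.02) * rng.uniform(0.8, 1.2)
                if t.outcome != "omission"
                else 0.0
                for t in session.trials
            ]
        )
        truth = synth.TransientGroundTruth(amplitudes=amps)
        rec, _ = synth.gen_photometry(
            session, truth, motion_scale=0.5, noise_sd=0.01,
            fs=sc.photometry_fs_hz, seed=seed_phot,
        )
        dff = photometry.process_recording(rec)
        aligned = photometry.segment_trials(
            dff, session, pre_s=config.photometry.pre_s, post_s=config.photometry.post_s
        )
        feats = photometry.trial_features(aligned)
        _write_csv(out / "photometry_features.csv", feats)
        return feats

    features = run_stage("photometry", _photometry)

    # --- decoding -----------------------------------------------------------
    seed_dec = stage_seed(config.seed, "decoding")
    manifest.stage_seeds["decoding"] = seed_dec

    def _decoding():
        X_df, y = decoding.features_and_labels(features)
        X = decoding.normalize_features(X_df).to_numpy()
        dc = config.decoding
        if min(np.bincount(y)) < dc.cv_folds:
            _write_json(out / "decoding.json",
                        {"skipped": "too few minority trials for stratified CV"})
            return None
        real = decoding.crossval_auc(
            X, y, k=dc.cv_folds, repeats=dc.cv_repeats,
            row_subsample=dc.row_subsample, col_subsample=dc.col_subsample,
            max_depth=dc.max_depth, n_rounds=dc.n_rounds,
            learning_rate=dc.learning_rate, seed=seed_dec,
            rebalance_in_folds=dc.rebalance_in_folds,
            k_neighbors=dc.smote_k_neighbors,
        )
        full = decoding.null_model(
            X, y, real_report=real, k=dc.cv_folds, repeats=dc.cv_repeats,
            row_subsample=dc.row_subsample, col_subsample=dc.col_subsample,
            max_depth=dc.max_depth, n_rounds=dc.n_rounds,
            learning_rate=dc.learning_rate, seed=seed_dec,
            rebalance_in_folds=dc.rebalance_in_folds,
            k_neighbors=dc.smote_k_neighbors,
        )
        _write_json(
            out / "decoding.json",
            {
                "fold_aucs": list(np.round(full.fold_aucs, 12)),
                "mean_auc": round(full.mean_auc, 12),
                "null_mean_auc": round(full.null_mean_auc, 12),
                "p_value": round(full.p_value, 12),
            },
        )
        return full

    run_stage("decoding", _decoding)

    # --- laminar CSD --------------------------------------------------------
    seed_lam = stage_seed(config.seed, "laminar")
    manifest.stage_seeds["laminar"] = seed_lam

    def _laminar():
        sweeps, _truth = synth.gen_laminar(
            sink_channel=8, source_channels=(6, 10), noise_sd=1e-6, seed=seed_lam
        )
        win = csd.ComponentWindow("L23_sink", 7, 9, 0.02, 0.04, "sink")
        curve = csd.amplitude_curve(sweeps, win)
        _write_csv(
            out / "csd_curves.csv",
            pd.DataFrame(
                {"stim_intensity_uA": list(curve), "peak_v_per_mm2": list(curve.values())}
            ),
        )
        return curve

    run_stage("laminar", _laminar)

    # --- IPSP failures ------------------------------------------------------
    seed_ipsp = stage_seed(config.seed, "ipsp")
    manifest.stage_seeds["ipsp"] = seed_ipsp

    def _ipsp():
        sweeps = synth.gen_ipsp_sweeps(
            n_trials=5, p_release=0.8, noise_sd_mv=0.02, seed=seed_ipsp
        )
        report = intracellular.ipsp_failures(
            sweeps,
            failure_threshold_mv=config.intracellular.failure_threshold_mv,
            window_s=config.intracellular.response_window_s,
            baseline_s=config.intracellular.baseline_window_s,
        )
        _write_json(
            out / "ipsp_failures.json",
            {
                "per_sweep_pct": report.per_sweep_pct,
                "per_cell_mean_pct": report.per_cell_mean_pct,
                "n_pulses": report.n_pulses,
            },
        )
        return report

    run_stage("ipsp", _ipsp)

    # --- spike reduction ----------------------------------------------------
    seed_spk = stage_seed(config.seed, "spikes")
    manifest.stage_seeds["spikes"] = seed_spk

    def _spikes():
        current = synth.gen_noisy_current(seed=seed_spk)
        sweeps = synth.gen_spike_sweeps(
            current, inhibition_fraction=0.5, n_trials=5, seed=seed_spk
        )
        counts = {
            cond: [
                intracellular.detect_spikes(
                    sw.vm,
                    config.intracellular.spike_threshold_mv,
                    config.intracellular.refractory_s,
                ).size
                for sw in sweeps
                if sw.condition == cond
            ]
            for cond in ("no_light", "train_40hz")
        }
        result = intracellular.spike_reduction(
            counts["no_light"], counts["train_40hz"]
        )
        _write_json(out / "spike_reduction.json", result)
        return result

    run_stage("spikes", _spikes)

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.outputs[f.name] = _sha256(f)
    manifest.save(out / "manifest.json")
    return manifest


def report(out_dir: str | Path) -> pd.DataFrame:
    """One-row-per-metric summary table assembled from pipeline outputs.

    Regeneration is idempotent: the table is a pure function of the files
    on disk.  Missing (skipped) stages are omitted with a note row.
    """
    out = Path(out_dir)
    rows = []

    def add(stage, metric, value):
        rows.append({"stage": stage, "metric": metric, "value": value})

    beh = out / "behavior.json"
    if beh.exists():
        data = json.loads(beh.read_text())
        add("behavior", "repetitive_score", data["repetitive_score"])
        add("behavior", "n_trials", data["n_trials"])
        add("behavior", "engaged", float(data["engaged"]))
    sz = out / "seizures.json"
    if sz.exists():
        data = json.loads(sz.read_text())
        add("seizure", "seizures_per_min", data["seizures_per_min"])
        add("seizure", "n_events", len(data["events"]))
    dec = out / "decoding.json"
    if dec.exists():
        data = json.loads(dec.read_text())
        if "skipped" in data:
            add("decoding", "note", data["skipped"])
        else:
            add("decoding", "mean_auc", data["mean_auc"])
            add("decoding", "null_mean_auc", data["null_mean_auc"])
            add("decoding", "p_value", data["p_value"])
    ipsp = out / "ipsp_failures.json"
    if ipsp.exists():
        add("ipsp", "per_cell_mean_failure_pct",
            json.loads(ipsp.read_text())["per_cell_mean_pct"])
    spk = out / "spike_reduction.json"
    if spk.exists():
        add("spikes", "spike_reduction_pct", json.loads(spk.read_text())["pct"])
    return pd.DataFrame(rows, columns=["stage", "metric", "value"])
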