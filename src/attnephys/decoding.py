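"""Trial-outcome decoding from per-trial photometry features.

Pipeline: extreme-outlier removal (trace SD > 10x the group mean SD),
min/max feature normalization (raw trace maxima/minima exempt), class
rebalancing to near 50:50 by SMOTE oversampling followed by Tomek-link
cleaning, then gradient-boosted tree classification under repeated
(k=10, n=3) stratified cross-validation with 80% row / 30% feature
subsampling per boosting iteration, scored by held-out ROC-AUC against a
shuffled-label null.

SMOTE synthesizes minority samples by interpolating, at a uniform random
fraction, between a minority point and one of its k nearest minority
neighbors (Euclidean distance on the normalized features).  A Tomek link
is a cross-class pair of mutual nearest neighbors; the majority member of
every link is removed.  Both are implemented here on sklearn
nearest-neighbor queries.

Rebalancing is applied inside each training fold only — never to held-out
data — so the null distribution stays centered at chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ranksums
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from xgboost import XGBClassifier

#: raw-extreme feature columns exempt from min/max normalization
NORMALIZATION_EXEMPT = ("base_min", "base_max", "cue_min", "cue_max")


def _child_seed(seed: int, *tags: int) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, tags)])
    return int(ss.generate_state(1)[0] % 2**31)


def features_and_labels(
    features: pd.DataFrame, drop_omissions: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a trial-features table into (X, y) for decoding.

    X keeps the ``base_*`` / ``cue_*`` summary-statistic columns; y is 1
    for correct, 0 for incorrect.  Omission trials are dropped by default.
    """
    df = features
    if drop_omissions and "outcome" in df.columns:
        df = df[df.outcome != "omission"]
    cols = [
        c for c in df.columns
        if c.startswith(("base_", "cue_")) and c != "cue_length_s"
    ]
    y = (df["outcome"] == "correct").to_numpy(dtype=int)
    return df[cols].reset_index(drop=True), y


def remove_outliers(
    traces: np.ndarray, factor: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop trials whose trace SD exceeds ``factor`` x the group mean SD.

    Strict inequality: a trial at exactly the factor is retained.  Returns
    (kept indices, dropped indices).
    """
    traces = np.asarray(traces, float)
    if traces.shape[0] < 3:
        raise ValueError("need at least 3 trials for outlier screening")
    sds = traces.std(axis=1, ddof=0)
    limit = factor * sds.mean()
    dropped = np.flatnonzero(sds > limit)
    kept = np.flatnonzero(sds <= limit)
    return kept, dropped


def normalize_features(
    X: pd.DataFrame, exempt: tuple[str, ...] = NORMALIZATION_EXEMPT
) -> pd.DataFrame:
    """Min/max normalize every column except the raw trace extremes.

    Normalized columns map to [0, 1] via (x - min) / (max - min); exempt
    columns pass through unchanged; constant columns are dropped with a
    warning.
    """
    out = {}
    dropped = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        if col in exempt:
            out[col] = v
            continue
        rng = v.max() - v.min()
        if rng == 0:
            dropped.append(col)
            continue
        out[col] = (v - v.min()) / rng
    if dropped:
        warnings.warn(f"normalize_features: dropped constant column(s) {dropped}",
                      stacklevel=2)
    return pd.DataFrame(out, index=X.index)


@dataclass
class ResampleResult:
    X: np.ndarray
    y: np.ndarray
    minority_fraction: float
    n_synthetic: int
    n_tomek_removed: int


def smote(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity by neighbor interpolation."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE needs exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y
    Xm = X[y == minority]
    if Xm.shape[0] <= k_neighbors:
        k = Xm.shape[0] - 1
        warnings.warn(
            f"smote: minority count {Xm.shape[0]} <= k={k_neighbors}; reducing k to {k}",
            stacklevel=2,
        )
        k_neighbors = k
    if k_neighbors < 1:
        raise ValueError("minority class too small for SMOTE")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)  # col 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, Xm.shape[0], n_needed)
    pick = rng.integers(1, k_neighbors + 1, n_needed)
    frac = rng.random(n_needed)[:, None]
    neighbors = Xm[idx[base, pick]]
    synthetic = Xm[base] + frac * (neighbors - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def tomek_links(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Indices of majority samples in Tomek links (cross-class mutual NN)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    majority = classes[np.argmax(counts)]
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    _, idx = nn.kneighbors(X)
    nearest = idx[:, 1]
    remove = []
    for i in np.flatnonzero(y == majority):
        j = nearest[i]
        if y[j] != y[i] and nearest[j] == i:
            remove.append(i)
    return np.asarray(remove, dtype=int)


def rebalance(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> ResampleResult:
    """SMOTE to parity then Tomek-link cleaning; near 50:50 balance out."""
    n_in = len(y)
    X_s, y_s = smote(X, y, k_neighbors=k_neighbors, seed=seed)
    remove = tomek_links(X_s, y_s)
    keep = np.setdiff1d(np.arange(len(y_s)), remove)
    X_out, y_out = X_s[keep], y_s[keep]
    _, counts = np.unique(y_out, return_counts=True)
    return ResampleResult(
        X=X_out,
        y=y_out,
        minority_fraction=float(counts.min() / counts.sum()),
        n_synthetic=len(y_s) - n_in,
        n_tomek_removed=len(remove),
    )


@dataclass
class DecodingReport:
    fold_aucs: np.ndarray
    mean_auc: float
    seed: int
    params: dict = field(default_factory=dict)
    null_fold_aucs: np.ndarray | None = None
    null_mean_auc: float | None = None
    p_value: float | None = None


def _fit_fold(
    X_tr, y_tr, X_te, params: dict, fold_seed: int, rebalance_in_folds: bool,
    k_neighbors: int,
) -> np.ndarray:
    if rebalance_in_folds and np.unique(y_tr).size == 2:
        res = rebalance(X_tr, y_tr, k_neighbors=k_neighbors, seed=fold_seed)
        X_tr, y_tr = res.X, res.y
    clf = XGBClassifier(
        max_depth=params["max_depth"],
        n_estimators=params["n_rounds"],
        learning_rate=params["learning_rate"],
        subsample=params["row_subsample"],
        colsample_bytree=params["col_subsample"],
        random_state=fold_seed,
        n_jobs=1,
        tree_method="hist",
        eval_metric="logloss",
    )
    clf.fit(X_tr, y_tr)
    return clf.predict_proba(X_te)[:, 1]


def crossval_auc(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    repeats: int = 3,
    row_subsample: float = 0.8,
    col_subsample: float = 0.3,
    max_depth: int = 3,
    n_rounds: int = 200,
    learning_rate: float = 0.1,
    seed: int = 0,
    rebalance_in_folds: bool = True,
    k_neighbors: int = 5,
    _permute_per_repeat: bool = False,
    _identity_permutation: bool = False,
) -> DecodingReport:
    """Repeated stratified k-fold ROC-AUC with boosted trees.

    Rebalancing (SMOTE + Tomek) runs inside each training fold only; the
    held-out fold is never resampled.  With ``rebalance_in_folds=False``
    the whole matrix is resampled once before cross-validation (the
    leakage-prone ordering, kept for comparison).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    params = {
        "max_depth": max_depth, "n_rounds": n_rounds, "learning_rate": learning_rate,
        "row_subsample": row_subsample, "col_subsample": col_subsample,
        "k": k, "repeats": repeats, "rebalance_in_folds": rebalance_in_folds,
    }
    if not rebalance_in_folds:
        res = rebalance(X, y, k_neighbors=k_neighbors, seed=_child_seed(seed, 99))
        X, y = res.X, res.y
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"need >= {k} samples per class for stratified {k}-fold CV, have {counts.min()}"
        )
    aucs = []
    for r in range(repeats):
        rep_seed = _child_seed(seed, r)
        y_run = y
        if _permute_per_repeat and not _identity_permutation:
            rng = np.random.default_rng(_child_seed(seed, r, 7))
            y_run = y[rng.permutation(len(y))]
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rep_seed)
        for f, (tr, te) in enumerate(skf.split(X, y_run)):
            if np.unique(y_run[tr]).size < 2 or np.unique(y_run[te]).size < 2:
                raise ValueError("stratification failure: a class is absent in a fold")
            prob = _fit_fold(
                X[tr], y_run[tr], X[te], params,
                _child_seed(seed, r, f), rebalance_in_folds, k_neighbors,
            )
            aucs.append(roc_auc_score(y_run[te], prob))
    aucs = np.asarray(aucs)
    return DecodingReport(
        fold_aucs=aucs, mean_auc=float(aucs.mean()), seed=seed, params=params
    )


def null_model(
    X: np.ndarray,
    y: np.ndarray,
    real_report: DecodingReport | None = None,
    identity_permutation: bool = False,
    **cv_kwargs,
) -> DecodingReport:
    """Shuffled-label null: labels permuted once per repeat, same pipeline.

    Compares real vs null per-fold AUCs by a rank-sum test when a real
    report is supplied.  ``identity_permutation=True`` is a test hook that
    makes the null identical to the real run.
    """
    null = crossval_auc(
        X, y, _permute_per_repeat=True, _identity_permutation=identity_permutation,
        **cv_kwargs,
    )
    if real_report is not None:
        stat = ranksums(real_report.fold_aucs, null.fold_aucs)
        return DecodingReport(
            fold_aucs=real_report.fold_aucs,
            mean_auc=real_report.mean_auc,
            seed=real_report.seed,
            params=real_report.params,
            null_fold_aucs=null.fold_aucs,
            null_mean_auc=null.mean_auc,
            p_value=float(stat.pvalue),
        )
    return null
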