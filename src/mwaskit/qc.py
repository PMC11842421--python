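"""Feature-level quality control, replicate summarization, transformation,
batch centering, auto-scaling and kNN imputation.

Filters applied per feature (strict inequalities):

* missing fraction, counted at the summarized sample level (a sample is
  missing only when all three replicate injections are absent), < 0.30;
* median technical-replicate CV (sample sd / mean, raw intensities) < 0.30;
* median of the three pairwise replicate Pearson correlations > 0.70.

Batch correction is per-feature, per-batch median centering on the log2
scale (a deterministic simplification of wavelet-based correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import FeatureTable

__all__ = [
    "QcThresholds",
    "TransformResult",
    "summarize_replicates",
    "replicate_cv",
    "replicate_pearson",
    "qc_metrics",
    "apply_qc",
    "log2_batch_center_autoscale",
    "knn_impute",
]


@dataclass(frozen=True)
class QcThresholds:
    max_missing_frac: float = 0.30
    max_median_cv: float = 0.30
    min_median_replicate_pearson: float = 0.70
    knn_k: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.max_missing_frac <= 1):
            raise ValueError("max_missing_frac must be in (0, 1]")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


# ---------------------------------------------------------------------------
# Replicate summaries
# ---------------------------------------------------------------------------


def summarize_replicates(table: FeatureTable) -> pd.DataFrame:
    """Median of observed replicates per (feature, sample); NaN if all absent."""
    cube = table.cube()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(cube, axis=2)
    return pd.DataFrame(med, index=table.feature_ids, columns=table.sample_ids)


def _cv_matrix(cube: np.ndarray) -> np.ndarray:
    """Per (feature, sample) replicate CV; NaN where <2 replicates observed."""
    obs = ~np.isnan(cube)
    n = obs.sum(axis=2)
    filled = np.where(obs, cube, 0.0)
    s = filled.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s / n
        ss = (np.where(obs, cube - mean[..., None], 0.0) ** 2).sum(axis=2)
        sd = np.sqrt(ss / (n - 1))
        cv = sd / mean
    cv[n < 2] = np.nan
    return cv


def replicate_cv(table: FeatureTable, feature_id: str) -> tuple[pd.Series, float]:
    """Per-sample replicate CVs for one feature and their median.

    CV is sample sd (n-1) over mean, on raw pre-log intensities; samples
    with fewer than two observed replicates are skipped.  Returns NaN
    median when no sample has >= 2 observed replicates (undefined -> the
    feature fails QC).
    """
    idx = table.feature_ids.index(feature_id)
    cv = _cv_matrix(table.cube()[idx : idx + 1])[0]
    per_sample = pd.Series(cv, index=table.sample_ids)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return per_sample, float(np.nanmedian(cv))


def _pearson_pairs(cube: np.ndarray) -> np.ndarray:
    """Pearson of each replicate pair across samples, shape (n_features, 3).

    Pair (i, j) uses samples where both members are observed; pairs with
    fewer than 3 usable samples or zero variance are NaN.
    """
    n_feat = cube.shape[0]
    pairs = [(0, 1), (0, 2), (1, 2)]
    out = np.full((n_feat, 3), np.nan)
    for p, (i, j) in enumerate(pairs):
        x, y = cube[:, :, i], cube[:, :, j]
        m = ~np.isnan(x) & ~np.isnan(y)
        n = m.sum(axis=1)
        xf, yf = np.where(m, x, 0.0), np.where(m, y, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mx = xf.sum(1) / n
            my = yf.sum(1) / n
            cov = (np.where(m, (x - mx[:, None]) * (y - my[:, None]), 0.0)).sum(1)
            vx = (np.where(m, (x - mx[:, None]) ** 2, 0.0)).sum(1)
            vy = (np.where(m, (y - my[:, None]) ** 2, 0.0)).sum(1)
            r = cov / np.sqrt(vx * vy)
        r[(n < 3) | (vx <= 0) | (vy <= 0)] = np.nan
        out[:, p] = r
    return out


def replicate_pearson(table: FeatureTable, feature_id: str) -> tuple[np.ndarray, float]:
    """The three pairwise replicate Pearsons for one feature and their median."""
    idx = table.feature_ids.index(feature_id)
    pairs = _pearson_pairs(table.cube()[idx : idx + 1])[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return pairs, float(np.nanmedian(pairs))


def qc_metrics(table: FeatureTable) -> pd.DataFrame:
    """Per-feature QC metrics: summarized missing fraction, median CV,
    median replicate Pearson."""
    cube = table.cube()
    all_absent = np.isnan(cube).all(axis=2)
    missing_frac = all_absent.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median_cv = np.nanmedian(_cv_matrix(cube), axis=1)
        median_pearson = np.nanmedian(_pearson_pairs(cube), axis=1)
    return pd.DataFrame(
        {
            "mz": table.mz,
            "rt": table.rt,
            "missing_frac": missing_frac,
            "median_cv": median_cv,
            "median_pearson": median_pearson,
        },
        index=table.feature_ids,
    )


def apply_qc(
    table: FeatureTable, thresholds: QcThresholds = QcThresholds()
) -> tuple[FeatureTable, pd.DataFrame]:
    """Filter features on the three QC criteria; returns table + report.

    The report records each metric, the pass flag and the failure reasons
    (``missing``, ``cv``, ``pearson``; ``*_undefined`` when a metric could
    not be computed).  Permuting feature rows permutes the report rows
    identically.
    """
    report = qc_metrics(table)
    reasons = []
    for fid, row in report.iterrows():
        r = []
        if not row["missing_frac"] < thresholds.max_missing_frac:
            r.append("missing")
        if np.isnan(row["median_cv"]):
            r.append("cv_undefined")
        elif not row["median_cv"] < thresholds.max_median_cv:
            r.append("cv")
        if np.isnan(row["median_pearson"]):
            r.append("pearson_undefined")
        elif not row["median_pearson"] > thresholds.min_median_replicate_pearson:
            r.append("pearson")
        reasons.append(";".join(r))
    report["fail_reasons"] = reasons
    report["passed"] = report["fail_reasons"] == ""
    kept = report.index[report["passed"]]
    return table.subset(kept), report


# ---------------------------------------------------------------------------
# Transformation
# ---------------------------------------------------------------------------


@dataclass
class TransformResult:
    """log2 -> batch-centered -> auto-scaled matrix (observed entries only).

    ``mean``/``sd`` are the per-feature auto-scaling parameters on the
    batch-centered log2 scale, kept so downstream consumers can map values
    back to the log2 scale.  ``dropped`` lists constant features removed.
    """

    values: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    dropped: list[str] = field(default_factory=list)


def log2_batch_center_autoscale(
    matrix: pd.DataFrame, sample_batches: Mapping[str, str], ddof: int = 1
) -> TransformResult:
    """log2-transform, per-batch median-center and auto-scale each feature.

    Zeros are replaced by half the feature's minimum positive observed
    intensity before log2.  Features with zero variance are dropped and
    reported.  Missing entries stay missing (imputation is separate).
    """
    X = matrix.to_numpy(dtype=float).copy()
    if np.nanmin(X, initial=np.inf) < 0:
        raise ValueError("negative intensities cannot be log-transformed")
    obs = ~np.isnan(X)

    # half-minimum substitution for observed zeros
    pos = np.where(obs & (X > 0), X, np.inf)
    min_pos = pos.min(axis=1)
    zero_rows = np.where(obs & (X == 0))
    X[zero_rows] = 0.5 * min_pos[zero_rows[0]]
    all_zero = ~np.isfinite(min_pos)

    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(obs, np.log2(np.where(obs, X, 1.0)), np.nan)

    batches = np.array([sample_batches[s] for s in matrix.columns])
    for b in np.unique(batches):
        cols = batches == b
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(L[:, cols], axis=1)
        med = np.where(np.isnan(med), 0.0, med)
        L[:, cols] -= med[:, None]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(L, axis=1)
        sd = np.nanstd(L, axis=1, ddof=ddof)
    constant = all_zero | np.isnan(sd) | (sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (L - mean[:, None]) / sd[:, None]

    keep = ~constant
    dropped = list(matrix.index[constant])
    return TransformResult(
        values=pd.DataFrame(Z[keep], index=matrix.index[keep], columns=matrix.columns),
        mean=pd.Series(mean[keep], index=matrix.index[keep]),
        sd=pd.Series(sd[keep], index=matrix.index[keep]),
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# kNN imputation
# ---------------------------------------------------------------------------


def knn_impute(matrix: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing entries from the k nearest features.

    For feature ``f`` missing at sample ``s``: candidates are features
    observed at ``s`` that share at least one co-observed sample with
    ``f``; the distance is the Euclidean distance over co-observed samples
    normalized by their count (RMS difference); the imputed value is the
    inverse-distance-weighted mean of the k nearest candidates' values at
    ``s``.  Zero-distance candidates are used directly.  With no candidate
    at all, the feature mean (0 on auto-scaled data) is used and a warning
    is emitted.  Observed entries are never altered.
    """
    X = matrix.to_numpy(dtype=float).copy()
    M = ~np.isnan(X)
    rows = np.where((~M).any(axis=1))[0]
    if rows.size == 0:
        return matrix.copy()

    Xf = np.where(M, X, 0.0)
    Mf = M.astype(float)
    sq = Xf**2
    # squared distance over co-observed samples, via three matmuls
    C = Mf[rows] @ Mf.T
    S = sq[rows] @ Mf.T + Mf[rows] @ sq.T - 2.0 * (Xf[rows] @ Xf.T)
    S = np.clip(S, 0.0, None)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.sqrt(S / C)  # NaN where no co-observed sample

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        feat_mean = np.nanmean(X, axis=1)
    feat_mean = np.where(np.isnan(feat_mean), 0.0, feat_mean)

    for ridx, f in enumerate(rows):
        d_all = D[ridx].copy()
        d_all[f] = np.nan  # never use the feature itself
        for s in np.where(~M[f])[0]:
            usable = M[:, s] & ~np.isnan(d_all)
            if not usable.any():
                warnings.warn(
                    f"no imputation candidates for feature index {f} at sample index {s}; "
                    "using feature mean"
                )
                X[f, s] = feat_mean[f]
                continue
            cand = np.where(usable)[0]
            d = d_all[cand]
            zero = d == 0
            if zero.any():
                X[f, s] = X[cand[zero], s].mean()
                continue
            kk = min(k, cand.size)
            nn = np.argpartition(d, kk - 1)[:kk]
            w = 1.0 / d[nn]
            X[f, s] = float(np.dot(w, X[cand[nn], s]) / w.sum())
    return pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
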