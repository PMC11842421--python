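"""Per-feature logistic regression of exposure on adjusted intensity,
Benjamini-Hochberg FDR adjustment, and Manhattan-style export.

Confounders do not enter the logistic model: features are residualized
against them beforehand, so each fit is ``logit P(smoker) = a + b x``.
Perfect-separation fits are flagged and excluded from the FDR adjustment
rather than rescued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "LogisticResult",
    "logistic_fit",
    "logistic_fit_many",
    "bh_fdr",
    "associate",
    "manhattan_table",
]

_MAX_ABS_BETA = 25.0  # slope beyond this is treated as separation


@dataclass(frozen=True)
class LogisticResult:
    beta: float
    se: float
    p: float
    converged: bool
    separated: bool


def logistic_fit_many(
    y: np.ndarray, X: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> list[LogisticResult]:
    """Newton/IRLS fits of ``logit P(y=1) = a + b x`` for every column of X.

    All features share the outcome, so the 2x2 Newton step is vectorized
    across features.  Convergence is ``max |delta| < tol``; Wald p comes
    from ``b/se`` against the standard normal.  Constant features return
    ``beta=0, p=1``; runaway slopes are flagged as separation.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if X.shape[0] != y.size:
        raise ValueError("X rows must align with y")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValueError("y must be binary with both classes present")

    n, m = X.shape
    const = X.std(axis=0) == 0
    a = np.full(m, float(np.log(y.mean() / (1 - y.mean()))))
    b = np.zeros(m)
    active = ~const
    converged = np.zeros(m, dtype=bool)
    converged[const] = True

    for _ in range(max_iter):
        if not active.any():
            break
        eta = a[None, :] + X * b[None, :]
        mu = expit(np.clip(eta, -30, 30))
        w = mu * (1 - mu)
        r = y[:, None] - mu
        s0 = w.sum(axis=0)
        s1 = (w * X).sum(axis=0)
        s2 = (w * X * X).sum(axis=0)
        g0 = r.sum(axis=0)
        g1 = (r * X).sum(axis=0)
        det = s0 * s2 - s1 * s1
        det = np.where(np.abs(det) < 1e-300, np.nan, det)
        da = (s2 * g0 - s1 * g1) / det
        db = (s0 * g1 - s1 * g0) / det
        da = np.where(active & np.isfinite(da), da, 0.0)
        db = np.where(active & np.isfinite(db), db, 0.0)
        a += da
        b += db
        step = np.maximum(np.abs(da), np.abs(db))
        newly = active & (step < tol)
        converged |= newly
        active &= ~newly
        # stop following runaway (separated) fits
        active &= np.abs(b) <= 10 * _MAX_ABS_BETA

    separated = np.abs(b) > _MAX_ABS_BETA
    # final information matrix for standard errors
    eta = a[None, :] + X * b[None, :]
    mu = expit(np.clip(eta, -30, 30))
    w = mu * (1 - mu)
    s0 = w.sum(axis=0)
    s1 = (w * X).sum(axis=0)
    s2 = (w * X * X).sum(axis=0)
    det = s0 * s2 - s1 * s1
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.where(det > 0, s0 / det, np.inf))
        z = np.where(se > 0, b / se, 0.0)
    p = 2 * norm.sf(np.abs(z))

    out: list[LogisticResult] = []
    for j in range(m):
        if const[j]:
            out.append(LogisticResult(0.0, float("inf"), 1.0, True, False))
        elif separated[j]:
            out.append(
                LogisticResult(float(b[j]), float(se[j]), float("nan"), False, True)
            )
        else:
            out.append(
                LogisticResult(
                    float(b[j]), float(se[j]), float(p[j]), bool(converged[j]), False
                )
            )
    return out


def logistic_fit(y: np.ndarray, x: np.ndarray, **kwargs) -> LogisticResult:
    """Single-feature convenience wrapper around :func:`logistic_fit_many`."""
    return logistic_fit_many(y, np.asarray(x, dtype=float).reshape(-1, 1), **kwargs)[0]


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order.

    ``q_(i) = min_{j >= i} (m p_(j) / j)``, clipped to 1.  NaN entries
    (e.g. separation failures) are excluded from m and stay NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.clip(ranked, 0.0, 1.0)
    qv = np.empty(m)
    qv[order] = ranked
    q[ok] = qv
    return q


def associate(
    y: np.ndarray,
    matrix: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Logistic association of every matrix row (feature) with exposure.

    ``matrix`` is features x samples of adjusted intensities; ``meta``
    optionally supplies ``mz``/``rt``/``mode`` columns indexed by feature.
    Output rows carry beta, se, p, BH q (computed over non-separated rows)
    and the direction sign.
    """
    fits = logistic_fit_many(np.asarray(y), matrix.to_numpy(dtype=float).T)
    df = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "beta": [f.beta for f in fits],
            "se": [f.se for f in fits],
            "p": [f.p for f in fits],
            "separated": [f.separated for f in fits],
        }
    ).set_index("feature_id")
    df["fdr_q"] = bh_fdr(df["p"].to_numpy())
    df["direction"] = np.sign(df["beta"]).astype(int)
    if meta is not None:
        df = df.join(meta.reindex(df.index), how="left")
    return df


def manhattan_table(
    rows: pd.DataFrame, n_labels: int = 20, p_significant: float = 1e-3
) -> pd.DataFrame:
    """Type-2 Manhattan export: -log10 p vs retention time.

    Flags the ``n_labels`` smallest-p rows for labeling and marks rows at
    p below ``p_significant``.  Requires an ``rt`` column and a ``p``
    column; rows must be non-empty.
    """
    if rows.empty:
        raise ValueError("no rows to export")
    out = rows.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"])
    out["significant"] = out["p"] < p_significant
    out["label"] = False
    finite = out["p"].dropna()
    top = finite.nsmallest(min(n_labels, finite.size)).index
    out.loc[top, "label"] = True
    return out
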