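"""NIPALS PLS-DA (PLS1 against a centered class indicator), VIP scoring,
discriminative-feature selection, fold changes, and score-plot export.

The discriminant is fitted as univariate PLS1 on the centered smoker
indicator, which yields the same discriminative direction as two-class
PLS-DA without the dummy-matrix ambiguity.  Weight signs are flipped so
each score vector correlates non-negatively with the class indicator,
making the output stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PlsdaModel",
    "fit_plsda",
    "vip",
    "fold_change",
    "export_scores",
    "plot_scores",
]


@dataclass
class PlsdaModel:
    """Fitted PLS1 model.

    Per component ``a``: unit-norm weight ``W[:, a]``, score ``T[:, a]``,
    X-loading ``P[:, a]``, inner coefficient ``b[a]`` and explained-Y sum
    of squares ``ssy[a] = b_a^2 (t_a' t_a)``.  ``x_var`` is the fraction
    of X variance captured by each component (for axis labels).
    """

    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    b: np.ndarray
    ssy: np.ndarray
    x_var: np.ndarray
    vip_: np.ndarray
    feature_ids: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.W.shape[1]

    @property
    def n_features(self) -> int:
        return self.W.shape[0]


def fit_plsda(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int = 2,
    feature_ids: list[str] | None = None,
) -> PlsdaModel:
    """Fit NIPALS PLS1 of the centered binary ``y`` on ``X`` (samples x features).

    Per component: ``w = X'y/||X'y||``, ``t = Xw``, ``p = X't/(t't)``,
    ``b = y't/(t't)``; then X and y are deflated.  Requires both classes
    present and ``n_components`` no larger than the rank of X.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have inconsistent sample counts")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"y must be binary with both classes present; got {classes}")
    n, p = X.shape
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise ValueError(f"n_components={n_components} exceeds the rank bound of X")

    Xa = X - X.mean(axis=0)
    y0 = y - y.mean()
    ya = y0.copy()
    ssx_total = float((Xa**2).sum())

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    b = np.zeros(n_components)
    ssy = np.zeros(n_components)
    x_var = np.zeros(n_components)

    for a in range(n_components):
        w = Xa.T @ ya
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError(f"component {a + 1}: X carries no remaining Y covariance")
        w /= norm
        t = Xa @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValueError(f"component {a + 1}: degenerate score vector")
        pa = Xa.T @ t / tt
        ba = float(ya @ t) / tt
        # sign convention: score correlates non-negatively with the original y
        if float(t @ y0) < 0:
            w, t, pa, ba = -w, -t, -pa, -ba
        W[:, a], T[:, a], P[:, a], b[a] = w, t, pa, ba
        ssy[a] = ba**2 * tt
        x_var[a] = tt * float(pa @ pa) / ssx_total if ssx_total > 0 else 0.0
        Xa = Xa - np.outer(t, pa)
        ya = ya - ba * t

    model = PlsdaModel(
        W=W, T=T, P=P, b=b, ssy=ssy, x_var=x_var, vip_=np.empty(p), feature_ids=feature_ids
    )
    model.vip_ = vip(model)
    return model


def vip(model: PlsdaModel) -> np.ndarray:
    """Variable Importance in Projection.

    ``VIP_j = sqrt(p * sum_a ssy_a w_ja^2 / sum_a ssy_a)`` with unit-norm
    weights, so ``sum_j VIP_j^2 == n_features``.  Raises when no component
    explains any Y variance (constant y).
    """
    total = model.ssy.sum()
    if total <= 0:
        raise ValueError("VIP undefined: no explained Y variance")
    contrib = (model.W**2) @ model.ssy
    return np.sqrt(model.n_features * contrib / total)


def fold_change(log2_values: pd.DataFrame, smoker: np.ndarray) -> pd.Series:
    """Per-feature fold change, ``2**(mean smokers - mean non-smokers)`` of
    covariate-adjusted log2-scale intensities (features x samples)."""
    smoker = np.asarray(smoker, dtype=bool)
    if smoker.size != log2_values.shape[1]:
        raise ValueError("smoker mask does not align with matrix columns")
    if smoker.all() or not smoker.any():
        raise ValueError("fold change requires both classes")
    V = log2_values.to_numpy(dtype=float)
    diff = V[:, smoker].mean(axis=1) - V[:, ~smoker].mean(axis=1)
    return pd.Series(np.exp2(diff), index=log2_values.index)


def export_scores(
    model: PlsdaModel, sample_ids: list[str], smoker: np.ndarray
) -> pd.DataFrame:
    """Score-plot table: first two component scores plus class, per sample."""
    if model.n_components < 2:
        raise ValueError("score plot needs at least 2 components")
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "t1": model.T[:, 0],
            "t2": model.T[:, 1],
            "smoker": np.asarray(smoker, dtype=bool),
        }
    )


def _confidence_ellipse(points: np.ndarray, level: float = 0.95) -> tuple:
    """Center, axis half-lengths and rotation (deg) of a chi2(2df) covariance
    ellipse for one class's scores."""
    from scipy.stats import chi2

    center = points.mean(axis=0)
    cov = np.cov(points.T)
    evals, evecs = np.linalg.eigh(cov)
    radius = np.sqrt(chi2.ppf(level, df=2))
    half = radius * np.sqrt(np.maximum(evals, 0.0))
    angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
    return center, half, angle


def plot_scores(scores: pd.DataFrame, path: str, x_var: np.ndarray | None = None) -> None:
    """Optional score plot with 95% confidence ellipses per class (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse

    fig, ax = plt.subplots(figsize=(5, 4))
    for smoker, color, marker, label in (
        (False, "tab:blue", "o", "non-smoker"),
        (True, "tab:orange", "^", "smoker"),
    ):
        sub = scores[scores["smoker"] == smoker]
        ax.scatter(sub["t1"], sub["t2"], s=12, c=color, marker=marker, label=label, alpha=0.6)
        if len(sub) >= 3:
            center, half, angle = _confidence_ellipse(sub[["t1", "t2"]].to_numpy())
            ax.add_patch(
                Ellipse(
                    center,
                    2 * half[1],
                    2 * half[0],
                    angle=angle,
                    fill=False,
                    edgecolor=color,
                )
            )
    if x_var is not None:
        ax.set_xlabel(f"X-variate 1 ({100 * x_var[0]:.1f}%)")
        ax.set_ylabel(f"X-variate 2 ({100 * x_var[1]:.1f}%)")
    else:
        ax.set_xlabel("X-variate 1")
        ax.set_ylabel("X-variate 2")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
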