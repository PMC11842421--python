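"""Covariate residualization: remove confounder signal from every feature
by ordinary least squares before discovery analyses."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import (
    AGE_LEVELS,
    BIRTH_YEAR_LEVELS,
    RACE_LEVELS,
    SES_LEVELS,
    SEX_LEVELS,
    SampleRecord,
)

__all__ = ["build_design", "residualize"]

_FACTORS: dict[str, tuple] = {
    "race_ethnicity": RACE_LEVELS,
    "maternal_age": AGE_LEVELS,
    "birth_year_band": BIRTH_YEAR_LEVELS,
    "sex": SEX_LEVELS,
    "ses": SES_LEVELS,
}


def build_design(samples: Sequence[SampleRecord]) -> pd.DataFrame:
    """Intercept plus treatment-coded indicators for the five confounders.

    The first listed level of each factor is the reference (dropped);
    residuals do not depend on this choice.
    """
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    for factor, levels in _FACTORS.items():
        for level in levels[1:]:
            cols[f"{factor}[{level}]"] = np.array(
                [1.0 if getattr(s, factor) == level else 0.0 for s in samples]
            )
    return pd.DataFrame(cols, index=[s.sample_id for s in samples])


def residualize(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    exclude: set[str] | frozenset[str] = frozenset(),
) -> tuple[pd.DataFrame, list[str]]:
    """OLS residuals of every feature on the design matrix.

    ``matrix`` is features x samples (complete, imputed); ``design`` is
    samples x columns, rows aligned to the matrix columns.  Features in
    ``exclude`` (e.g. the exposure biomarkers) are passed through untouched
    and returned in the second element so downstream stages can flag them
    as non-discoverable.  Raises on a rank-deficient design, naming the
    aliased columns.
    """
    if list(matrix.columns) != list(design.index):
        design = design.reindex(matrix.columns)
        if design.isna().any().any():
            raise ValueError("design rows do not cover all matrix samples")
    D = design.to_numpy(dtype=float)
    q, r = np.linalg.qr(D)
    diag = np.abs(np.diag(r))
    tol = max(D.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    aliased = [design.columns[i] for i in np.where(diag < tol)[0]]
    if aliased:
        raise ValueError(f"design matrix is rank deficient; aliased columns: {aliased}")

    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("residualize requires a complete (imputed) matrix")
    passthrough = [f for f in matrix.index if f in exclude]
    # residual = X - Q Q' X, computed on the samples axis
    Xt = X.T  # samples x features
    resid = Xt - q @ (q.T @ Xt)
    out = pd.DataFrame(resid.T, index=matrix.index, columns=matrix.columns)
    for f in passthrough:
        out.loc[f] = matrix.loc[f]
    return out, passthrough
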