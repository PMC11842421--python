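"""Pathway enrichment directly from m/z features, mummichog-style.

Selected features are tentatively mapped to pathway metabolites through
adduct masses (10 ppm), an EASE score (hypergeometric right tail after
removing one hit) is computed per pathway, a resampling null is built by
drawing random feature lists of the same size, and observed EASE scores
are converted to adjusted p-values on the CDF of a gamma distribution
fitted to the pooled null scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .annotate import ADDUCT_SHIFTS
from .core_io import Mode, PathwayDB

__all__ = [
    "EnrichConfig",
    "MzMapping",
    "NullModel",
    "EnrichmentResult",
    "map_mz_to_metabolites",
    "ease_score",
    "permutation_null",
    "gamma_adjust",
    "enrich",
]

DEFAULT_MAP_TOL_PPM = 10.0


@dataclass(frozen=True)
class EnrichConfig:
    tol_ppm: float = DEFAULT_MAP_TOL_PPM
    permutations: int = 100
    min_overlap: int = 3
    alpha: float = 0.05
    seed: int = 0


@dataclass
class MzMapping:
    """Feature -> metabolite-set map plus the detected-metabolite universe."""

    feature_ids: list[str]
    # boolean incidence, features x metabolites (metabolite order = met_ids)
    incidence: np.ndarray
    met_ids: list[str]

    @property
    def universe(self) -> set[str]:
        hit = self.incidence.any(axis=0)
        return {m for m, h in zip(self.met_ids, hit) if h}

    def metabolites_of(self, feature_id: str) -> set[str]:
        i = self.feature_ids.index(feature_id)
        return {m for m, h in zip(self.met_ids, self.incidence[i]) if h}


def map_mz_to_metabolites(
    mzs: Sequence[float],
    feature_ids: Sequence[str],
    db: PathwayDB,
    mode: Mode,
    tol_ppm: float = DEFAULT_MAP_TOL_PPM,
) -> MzMapping:
    """Map each feature m/z to every pathway metabolite with an adduct mass
    within ``tol_ppm``; isobaric ambiguity is preserved (a feature may map
    to several metabolites)."""
    if not db.pathways:
        raise ValueError("empty pathway database")
    met_ids = sorted(db.metabolite_masses)
    masses = np.array([db.metabolite_masses[m] for m in met_ids])
    shifts = np.array(list(ADDUCT_SHIFTS[mode].values()))
    # theoretical m/z per (metabolite, adduct), flattened and sorted
    theo = (masses[:, None] + shifts[None, :]).ravel()
    met_idx = np.repeat(np.arange(len(met_ids)), len(shifts))
    valid = theo > 0
    theo, met_idx = theo[valid], met_idx[valid]
    order = np.argsort(theo)
    theo, met_idx = theo[order], met_idx[order]

    mz_arr = np.asarray(mzs, dtype=float)
    tol = tol_ppm * 1e-6
    lo = np.searchsorted(theo, mz_arr / (1 + tol), side="left")
    hi = np.searchsorted(theo, mz_arr / (1 - tol), side="right")
    incidence = np.zeros((len(mz_arr), len(met_ids)), dtype=bool)
    for i, (a, b) in enumerate(zip(lo, hi)):
        if b > a:
            incidence[i, met_idx[a:b]] = True
    return MzMapping(feature_ids=list(feature_ids), incidence=incidence, met_ids=met_ids)


def ease_score(k: int, m: int, n: int, N: int) -> float:
    """EASE p-value: hypergeometric right tail after removing one hit.

    ``p = P(X >= k - 1)`` with ``X ~ Hypergeometric(N, m, n)`` — population
    N mappable metabolites, m in the pathway, n drawn as significant.
    ``k <= 1`` gives 1 by construction.
    """
    if not (0 <= k <= min(m, n)) or m > N or n > N or min(k, m, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, m={m}, n={n}, N={N}")
    if k <= 1:
        return 1.0
    return float(stats.hypergeom(M=N, n=m, N=n).sf(k - 2))


@dataclass
class NullModel:
    """Gamma model of pooled permutation EASE scores.

    The pool keeps only informative entries (overlap >= 2; no-overlap
    permutations give a constant EASE score of 1 that a continuous gamma
    cannot represent).  When the pool is too small or degenerate the model
    falls back to the empirical CDF of whatever was pooled.
    """

    n_permutations: int
    pooled: np.ndarray
    shape: float | None = None
    scale: float | None = None
    empirical_fallback: bool = False

    MIN_POOL = 50

    def cdf(self, x: float | np.ndarray) -> np.ndarray:
        if self.empirical_fallback:
            xs = np.atleast_1d(np.asarray(x, dtype=float))
            return np.array([(self.pooled <= v).mean() for v in xs])
        if self.shape is None:
            raise ValueError("null model is not fitted")
        return stats.gamma.cdf(x, a=self.shape, scale=self.scale)


def _pathway_matrix(db: PathwayDB, met_ids: Sequence[str]) -> tuple[list[str], np.ndarray]:
    pos = {m: i for i, m in enumerate(met_ids)}
    names = sorted(db.pathways)
    mat = np.zeros((len(names), len(met_ids)), dtype=bool)
    for r, name in enumerate(names):
        for m in db.pathways[name]:
            if m in pos:
                mat[r, pos[m]] = True
    return names, mat


def permutation_null(
    mapping: MzMapping,
    db: PathwayDB,
    n_selected: int,
    n_permutations: int = 100,
    seed: int = 0,
) -> NullModel:
    """Resampling null: draw ``n_selected`` features uniformly without
    replacement from the detected features, map them, and score every
    pathway; pool the informative EASE scores and fit a gamma (MLE,
    location fixed at 0, values clipped to [1e-12, 1]).

    A continuous gamma cannot represent the point mass at 1 produced by
    no-overlap permutations, so only informative entries (overlap >= 2)
    enter the pool; permutation blocks of ``n_permutations`` are drawn
    until the pool reaches ``NullModel.MIN_POOL`` (at most 10 blocks).
    A still-degenerate pool falls back to the empirical CDF.
    """
    F = mapping.incidence.shape[0]
    if n_selected > F:
        raise ValueError(f"n_selected={n_selected} exceeds detected features={F}")
    rng = np.random.default_rng(seed)
    detected = mapping.incidence.any(axis=0)
    N = int(detected.sum())
    names, pmat = _pathway_matrix(db, mapping.met_ids)
    m_per_path = (pmat & detected[None, :]).sum(axis=1)

    pool: list[float] = []
    all_values: list[float] = []
    total_perms = 0
    for _block in range(10):
        for _ in range(n_permutations):
            sel = rng.choice(F, size=n_selected, replace=False)
            hit = mapping.incidence[sel].any(axis=0)
            n_sig = int(hit.sum())
            ks = (pmat & hit[None, :]).sum(axis=1)
            for r in range(len(names)):
                if m_per_path[r] == 0:
                    continue
                p = ease_score(int(ks[r]), int(m_per_path[r]), n_sig, N)
                all_values.append(p)
                if ks[r] >= 2:
                    pool.append(p)
        total_perms += n_permutations
        if len(pool) >= NullModel.MIN_POOL:
            break

    if len(pool) >= 30:
        values = np.clip(np.array(pool), 1e-12, 1.0)
        if not np.allclose(values, values[0]):
            shape, _, scale = stats.gamma.fit(values, floc=0)
            return NullModel(
                n_permutations=total_perms,
                pooled=values,
                shape=float(shape),
                scale=float(scale),
            )
    values = np.clip(np.array(pool if pool else all_values), 1e-12, 1.0)
    return NullModel(
        n_permutations=total_perms,
        pooled=values if values.size else np.array([1.0]),
        empirical_fallback=True,
    )


def gamma_adjust(ease_p: float, null: NullModel) -> float:
    """Adjusted p = gamma CDF of the observed EASE score under the null model;
    monotone non-decreasing in ``ease_p``."""
    return float(np.atleast_1d(null.cdf(ease_p))[0])


@dataclass
class EnrichmentResult:
    pathway: str
    overlap_size: int  # k: significant-list metabolites in the pathway
    pathway_size: int  # m: pathway metabolites mappable to any detected feature
    ease_p: float
    gamma_adjusted_p: float
    significant: bool


def enrich(
    selected_ids: Sequence[str],
    detected_mzs: Sequence[float],
    detected_ids: Sequence[str],
    db: PathwayDB,
    mode: Mode,
    cfg: EnrichConfig = EnrichConfig(),
) -> list[EnrichmentResult]:
    """Enrichment of the selected features against the detected universe.

    ``selected_ids`` must be a subset of ``detected_ids``.  Only pathways
    with overlap >= ``cfg.min_overlap`` are reported, sorted by adjusted p.
    """
    id_pos = {f: i for i, f in enumerate(detected_ids)}
    missing = [f for f in selected_ids if f not in id_pos]
    if missing:
        raise ValueError(f"selected features not among detected: {missing[:5]}")
    if not selected_ids:
        return []

    mapping = map_mz_to_metabolites(detected_mzs, detected_ids, db, mode, cfg.tol_ppm)
    detected_hit = mapping.incidence.any(axis=0)
    N = int(detected_hit.sum())
    if N == 0:
        return []
    sel_rows = np.array([id_pos[f] for f in selected_ids])
    sig_hit = mapping.incidence[sel_rows].any(axis=0)
    n_sig = int(sig_hit.sum())

    names, pmat = _pathway_matrix(db, mapping.met_ids)
    m_per_path = (pmat & detected_hit[None, :]).sum(axis=1)
    k_per_path = (pmat & sig_hit[None, :]).sum(axis=1)

    null = permutation_null(
        mapping, db, n_selected=len(selected_ids), n_permutations=cfg.permutations, seed=cfg.seed
    )

    results: list[EnrichmentResult] = []
    for r, name in enumerate(names):
        k, m = int(k_per_path[r]), int(m_per_path[r])
        if k < cfg.min_overlap:
            continue
        p = ease_score(k, m, n_sig, N)
        adj = gamma_adjust(p, null)
        results.append(
            EnrichmentResult(
                pathway=name,
                overlap_size=k,
                pathway_size=m,
                ease_p=p,
                gamma_adjusted_p=adj,
                significant=adj < cfg.alpha,
            )
        )
    results.sort(key=lambda r: (r.gamma_adjusted_p, r.pathway))
    return results
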