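import math

import numpy as np
import pytest
from scipy import stats

from mwaskit.annotate import ADDUCT_SHIFTS
from mwaskit.core_io import Mode, PathwayDB
from mwaskit.pathway import (
    NullModel,
    ease_score,
    enrich,
    gamma_adjust,
    map_mz_to_metabolites,
    permutation_null,
)


def _hypergeom_tail_bruteforce(k_min, m, n, N):
    """P(X >= k_min) by exact enumeration of the hypergeometric pmf."""
    total = 0.0
    for k in range(max(k_min, max(0, n - (N - m))), min(m, n) + 1):
        total += math.comb(m, k) * math.comb(N - m, n - k) / math.comb(N, n)
    return total


# ---------------------------------------------------------------------------
# EASE score
# ---------------------------------------------------------------------------


def test_ease_k_at_most_one_is_one():
    assert ease_score(0, 10, 10, 100) == 1.0
    assert ease_score(1, 10, 10, 100) == 1.0


def test_ease_worked_example():
    expected = _hypergeom_tail_bruteforce(3, 10, 10, 100)
    assert ease_score(4, 10, 10, 100) == pytest.approx(expected, rel=1e-12)


def test_ease_certain_event():
    assert ease_score(5, 5, 5, 5) == pytest.approx(1.0)


def test_ease_inconsistent_counts():
    with pytest.raises(ValueError):
        ease_score(5, 4, 10, 100)
    with pytest.raises(ValueError):
        ease_score(2, 300, 10, 100)


def test_ease_exhaustive_small_universes():
    """Against brute-force enumeration for all (k, m, n, N) with N <= 12."""
    for N in range(1, 13):
        for m in range(N + 1):
            for n in range(N + 1):
                for k in range(min(m, n) + 1):
                    got = ease_score(k, m, n, N)
                    want = 1.0 if k <= 1 else _hypergeom_tail_bruteforce(k - 1, m, n, N)
                    assert got == pytest.approx(want, rel=1e-9), (k, m, n, N)


def test_ease_non_increasing_in_k():
    for m, n, N in [(10, 10, 100), (5, 8, 30), (20, 15, 60)]:
        vals = [ease_score(k, m, n, N) for k in range(min(m, n) + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# m/z -> metabolite mapping
# ---------------------------------------------------------------------------


def _db(masses, pathways=None):
    mm = {f"m{i}": v for i, v in enumerate(masses)}
    pws = pathways or {"P": frozenset(mm)}
    return PathwayDB(pathways=pws, metabolite_masses=mm)


def test_map_preserves_isobaric_ambiguity():
    shift = ADDUCT_SHIFTS[Mode.HILIC_POS]["[M+H]+"]
    mass = 300.0
    db = _db([mass, mass * (1 + 1e-6)])  # two isobars within 10 ppm
    mapping = map_mz_to_metabolites([mass + shift], ["f0"], db, Mode.HILIC_POS)
    assert mapping.metabolites_of("f0") == {"m0", "m1"}


def test_map_no_match_is_empty():
    db = _db([500.0])
    mapping = map_mz_to_metabolites([123.456], ["f0"], db, Mode.HILIC_POS)
    assert mapping.metabolites_of("f0") == set()
    assert mapping.universe == set()


def test_map_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    masses = rng.uniform(100, 900, size=50)
    db = _db(masses)
    mzs = rng.uniform(85, 1275, size=80)
    # salt in guaranteed matches
    shifts = list(ADDUCT_SHIFTS[Mode.C18_NEG].values())
    for i in range(20):
        mzs[i] = masses[rng.integers(50)] + shifts[rng.integers(len(shifts))]
    ids = [f"f{i}" for i in range(80)]
    mapping = map_mz_to_metabolites(mzs, ids, db, Mode.C18_NEG, tol_ppm=10)
    met_ids = sorted(db.metabolite_masses)
    for i, mz in enumerate(mzs):
        expected = set()
        for mid in met_ids:
            for shift in shifts:
                theo = db.metabolite_masses[mid] + shift
                if theo > 0 and abs(1e6 * (mz - theo) / theo) <= 10:
                    expected.add(mid)
        assert mapping.metabolites_of(ids[i]) == expected


def test_map_empty_db_rejected():
    with pytest.raises(ValueError, match="empty"):
        map_mz_to_metabolites([100.0], ["f0"], _db([]).__class__(pathways={}, metabolite_masses={}), Mode.HILIC_POS)


# ---------------------------------------------------------------------------
# permutation null + gamma adjustment
# ---------------------------------------------------------------------------


def _structured_db_and_features(rng, n_features=300, n_paths=5, size=25):
    shifts = list(ADDUCT_SHIFTS[Mode.HILIC_POS].values())
    mzs = rng.uniform(85, 1275, size=n_features)
    masses = {}
    pathways = {}
    c = 0
    for p in range(n_paths):
        members = set()
        for _ in range(size):
            mid = f"m{c}"
            c += 1
            src = mzs[rng.integers(n_features)]
            masses[mid] = src - shifts[rng.integers(len(shifts))]
            members.add(mid)
        pathways[f"P{p}"] = frozenset(members)
    db = PathwayDB(pathways=pathways, metabolite_masses=masses)
    ids = [f"f{i}" for i in range(n_features)]
    return db, mzs, ids


def test_permutation_null_deterministic():
    rng = np.random.default_rng(4)
    db, mzs, ids = _structured_db_and_features(rng)
    mapping = map_mz_to_metabolites(mzs, ids, db, Mode.HILIC_POS)
    n1 = permutation_null(mapping, db, n_selected=30, n_permutations=50, seed=11)
    n2 = permutation_null(mapping, db, n_selected=30, n_permutations=50, seed=11)
    np.testing.assert_array_equal(n1.pooled, n2.pooled)
    assert n1.shape == n2.shape and n1.scale == n2.scale


def test_permutation_null_size_guard():
    rng = np.random.default_rng(5)
    db, mzs, ids = _structured_db_and_features(rng, n_features=50)
    mapping = map_mz_to_metabolites(mzs, ids, db, Mode.HILIC_POS)
    with pytest.raises(ValueError, match="exceeds"):
        permutation_null(mapping, db, n_selected=51)


def test_gamma_adjust_monotone_and_median():
    rng = np.random.default_rng(6)
    db, mzs, ids = _structured_db_and_features(rng)
    mapping = map_mz_to_metabolites(mzs, ids, db, Mode.HILIC_POS)
    null = permutation_null(mapping, db, n_selected=40, n_permutations=60, seed=3)
    grid = np.linspace(1e-6, 1.0, 50)
    vals = [gamma_adjust(p, null) for p in grid]
    assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))
    if not null.empirical_fallback:
        med = stats.gamma.ppf(0.5, a=null.shape, scale=null.scale)
        assert gamma_adjust(float(med), null) == pytest.approx(0.5, abs=1e-9)
        # oracle CDF equality on the grid
        np.testing.assert_allclose(
            vals, stats.gamma.cdf(grid, a=null.shape, scale=null.scale), atol=1e-12
        )
    assert gamma_adjust(0.0, null) <= 1e-6


def test_gamma_adjust_preserves_ranking():
    rng = np.random.default_rng(7)
    db, mzs, ids = _structured_db_and_features(rng)
    mapping = map_mz_to_metabolites(mzs, ids, db, Mode.HILIC_POS)
    null = permutation_null(mapping, db, n_selected=30, n_permutations=60, seed=5)
    ps = sorted(rng.random(10))
    adj = [gamma_adjust(p, null) for p in ps]
    assert adj == sorted(adj)


def test_null_calibration_adjusted_p_approximately_uniform():
    """Observed lists drawn from the null itself: over 20 seeds the fraction
    of pathway adjusted p-values below 0.05 is <= 0.10."""
    rng = np.random.default_rng(20)
    db, mzs, ids = _structured_db_and_features(rng, n_features=400)
    mapping = map_mz_to_metabolites(mzs, ids, db, Mode.HILIC_POS)
    n_sel = 40
    total = below = 0
    names, pmat = None, None
    from mwaskit.pathway import _pathway_matrix

    names, pmat = _pathway_matrix(db, mapping.met_ids)
    detected = mapping.incidence.any(axis=0)
    N = int(detected.sum())
    m_per = (pmat & detected[None, :]).sum(axis=1)
    for seed in range(20):
        null = permutation_null(mapping, db, n_selected=n_sel, n_permutations=60, seed=seed)
        draw_rng = np.random.default_rng(1000 + seed)
        sel = draw_rng.choice(len(ids), size=n_sel, replace=False)
        hit = mapping.incidence[sel].any(axis=0)
        n_sig = int(hit.sum())
        ks = (pmat & hit[None, :]).sum(axis=1)
        for r in range(len(names)):
            if m_per[r] == 0:
                continue
            p = ease_score(int(ks[r]), int(m_per[r]), n_sig, N)
            adj = gamma_adjust(p, null)
            total += 1
            below += adj < 0.05
    assert total >= 80
    assert below / total <= 0.10


def test_empirical_fallback_on_degenerate_pool():
    null = NullModel(n_permutations=10, pooled=np.full(40, 1.0), empirical_fallback=True)
    assert float(null.cdf(1.0)[0]) == 1.0
    assert float(null.cdf(0.5)[0]) == 0.0


# ---------------------------------------------------------------------------
# enrich
# ---------------------------------------------------------------------------


def test_enrich_empty_selection():
    rng = np.random.default_rng(8)
    db, mzs, ids = _structured_db_and_features(rng)
    assert enrich([], mzs, ids, db, Mode.HILIC_POS) == []


def test_enrich_selected_must_be_subset():
    rng = np.random.default_rng(9)
    db, mzs, ids = _structured_db_and_features(rng)
    with pytest.raises(ValueError, match="not among detected"):
        enrich(["nope"], mzs, ids, db, Mode.HILIC_POS)


def test_enrich_recovers_planted_pathway(smoke_pipeline, smoke_sim):
    res = smoke_pipeline.modes[Mode.HILIC_POS]
    planted = smoke_sim.truth["planted_pathway"]
    sig = [r.pathway for r in res.enrichment if r.significant]
    assert planted in sig
    hit = next(r for r in res.enrichment if r.pathway == planted)
    assert hit.overlap_size >= 3
    assert 0 <= hit.ease_p <= 1 and 0 <= hit.gamma_adjusted_p <= 1
    assert hit.overlap_size <= hit.pathway_size


def test_enrich_results_sorted_and_filtered(smoke_pipeline):
    for res in smoke_pipeline.modes.values():
        adj = [r.gamma_adjusted_p for r in res.enrichment]
        assert adj == sorted(adj)
        assert all(r.overlap_size >= 3 for r in res.enrichment)
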