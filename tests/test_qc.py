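import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr

from mwaskit.qc import (
    QcThresholds,
    apply_qc,
    knn_impute,
    log2_batch_center_autoscale,
    qc_metrics,
    replicate_cv,
    replicate_pearson,
    summarize_replicates,
)

# ---------------------------------------------------------------------------
# replicate CV
# ---------------------------------------------------------------------------


def test_cv_identical_replicates_zero(make_table):
    table = make_table(np.full((1, 4, 3), 2.0))
    _, med = replicate_cv(table, table.feature_ids[0])
    assert med == 0.0


def test_cv_hand_computation(make_table):
    # replicates (1,2,3): sample sd 1, mean 2 -> CV 0.5
    table = make_table(np.tile([1.0, 2.0, 3.0], (1, 4, 1)))
    per_sample, med = replicate_cv(table, table.feature_ids[0])
    assert np.allclose(per_sample.dropna(), 0.5)
    assert med == pytest.approx(0.5)


def test_cv_skips_samples_with_single_replicate(make_table):
    vals = np.tile([2.0, 2.0, 2.0], (1, 3, 1)).astype(float)
    vals[0, 0, 1:] = np.nan  # one observed replicate: skipped
    vals[0, 1] = [1.0, 2.0, 3.0]
    table = make_table(vals)
    per_sample, med = replicate_cv(table, table.feature_ids[0])
    assert np.isnan(per_sample.iloc[0])
    assert med == pytest.approx(0.25)  # median of (0.5, 0)


def test_cv_undefined_when_no_sample_has_two_replicates(make_table):
    vals = np.full((1, 3, 3), np.nan)
    vals[:, :, 0] = 5.0
    table = make_table(vals)
    _, med = replicate_cv(table, table.feature_ids[0])
    assert np.isnan(med)


# ---------------------------------------------------------------------------
# replicate Pearson
# ---------------------------------------------------------------------------


def test_pearson_identical_replicates(make_table):
    base = np.linspace(1, 10, 10)
    table = make_table(np.stack([base, base, base], axis=-1)[None])
    _, med = replicate_pearson(table, table.feature_ids[0])
    assert med == pytest.approx(1.0)


def test_pearson_anticorrelated_pair(make_table):
    base = np.linspace(1, 10, 10)
    cube = np.stack([base, base[::-1], base], axis=-1)[None]
    table = make_table(cube)
    pairs, _ = replicate_pearson(table, table.feature_ids[0])
    assert pairs[0] == pytest.approx(-1.0)  # rep1 vs rep2
    assert pairs[1] == pytest.approx(1.0)  # rep1 vs rep3


def test_pearson_matches_scipy_oracle(make_table):
    rng = np.random.default_rng(5)
    cube = rng.lognormal(8, 1, size=(1, 10, 3))
    cube[0, 2, 1] = np.nan
    table = make_table(cube)
    pairs, med = replicate_pearson(table, table.feature_ids[0])
    expected = []
    for i, j in [(0, 1), (0, 2), (1, 2)]:
        x, y = cube[0, :, i], cube[0, :, j]
        m = ~np.isnan(x) & ~np.isnan(y)
        expected.append(pearsonr(x[m], y[m]).statistic)
    np.testing.assert_allclose(pairs, expected, atol=1e-12)
    assert med == pytest.approx(np.median(expected))


def test_pearson_undefined_with_too_few_samples(make_table):
    table = make_table(np.random.default_rng(0).lognormal(8, 1, (1, 2, 3)))
    _, med = replicate_pearson(table, table.feature_ids[0])
    assert np.isnan(med)


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------


def test_summarize_median_and_missing(make_table):
    vals = np.array([[[1.0, 2.0, 4.0], [np.nan, 3.0, 5.0], [np.nan] * 3]])
    table = make_table(vals)
    s = summarize_replicates(table)
    assert s.iloc[0, 0] == 2.0
    assert s.iloc[0, 1] == 4.0
    assert np.isnan(s.iloc[0, 2])


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------


def _engineered_table(make_table, rng=None):
    """10 features: 5 engineered to fail exactly one criterion each, 5 passing."""
    rng = rng or np.random.default_rng(42)
    n_samp = 20
    base = rng.lognormal(10, 1, size=n_samp)

    def good_feature(scale=1.0):
        sample_level = base * rng.lognormal(0, 0.8, size=n_samp) * scale
        return sample_level[:, None] * rng.normal(1, 0.02, size=(n_samp, 3))

    cube = np.stack(
        [good_feature(s) for s in (1.0, 2.0, 0.5, 1.5, 3.0)]
        + [good_feature() for _ in range(5)]
    )
    # feature 5: > 30% of samples entirely absent
    cube[5, :8, :] = np.nan
    # feature 6: huge replicate CV
    cube[6] = cube[6] * rng.lognormal(0, 1.0, size=(n_samp, 3))
    # feature 7: replicates uncorrelated across samples
    cube[7] = rng.lognormal(10, 0.02, size=(n_samp, 3))
    # feature 8: missing fraction just over threshold (7/20 = 35%)
    cube[8, :7, :] = np.nan
    # feature 9: anti-correlated replicate
    cube[9, :, 1] = cube[9, ::-1, 1]
    return make_table(cube), [5, 6, 7, 8, 9]


def test_apply_qc_engineered_fixture(make_table):
    table, bad = _engineered_table(make_table)
    filtered, report = apply_qc(table, QcThresholds())
    fids = table.feature_ids
    assert set(filtered.feature_ids) == {fids[i] for i in range(5)}
    assert report.loc[fids[5], "fail_reasons"] == "missing"
    assert "cv" in report.loc[fids[6], "fail_reasons"]
    assert "pearson" in report.loc[fids[7], "fail_reasons"]
    assert report.loc[fids[8], "fail_reasons"] == "missing"
    assert "pearson" in report.loc[fids[9], "fail_reasons"]


def test_apply_qc_vacuous_thresholds(make_table):
    table, _ = _engineered_table(make_table)
    # missing_frac < 1.0 holds for every feature here (none fully absent)
    thr = QcThresholds(max_missing_frac=1.0, max_median_cv=np.inf, min_median_replicate_pearson=-1.01)
    filtered, report = apply_qc(table, thr)
    assert filtered.feature_ids == table.feature_ids
    assert report["passed"].all()


def test_apply_qc_empty_table(make_table):
    table = make_table(np.empty((0, 2, 3)))
    filtered, report = apply_qc(table)
    assert len(filtered.features) == 0
    assert report.empty


def test_qc_order_independence(make_table):
    table, _ = _engineered_table(make_table)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(table.features))
    from mwaskit.core_io import FeatureTable

    permuted = FeatureTable(
        features=[table.features[i] for i in perm],
        injections=table.injections,
        intensities=table.intensities[perm],
    )
    r1 = qc_metrics(table)
    r2 = qc_metrics(permuted)
    pd.testing.assert_frame_equal(r1.loc[r2.index], r2)


# ---------------------------------------------------------------------------
# transform
# ---------------------------------------------------------------------------


def _matrix(values, batch=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    cols = [f"S{i}" for i in range(values.shape[1])]
    batches = {c: (batch[i] if batch else "B0") for i, c in enumerate(cols)}
    return pd.DataFrame(values, index=[f"f{i}" for i in range(values.shape[0])], columns=cols), batches


def test_batch_offset_removed():
    within = np.array([1.0, 2.0, 4.0, 8.0])
    m, batches = _matrix(
        np.concatenate([within, within * 32.0])[None], batch=["A"] * 4 + ["B"] * 4
    )
    res = log2_batch_center_autoscale(m, batches)
    v = res.values.iloc[0].to_numpy()
    assert v[:4] == pytest.approx(v[4:])  # +5 log2 offset removed entirely


def test_autoscale_mean_zero_sd_one():
    rng = np.random.default_rng(8)
    m, batches = _matrix(rng.lognormal(10, 1, size=(6, 15)))
    res = log2_batch_center_autoscale(m, batches)
    v = res.values.to_numpy()
    np.testing.assert_allclose(v.mean(axis=1), 0.0, atol=1e-8)
    np.testing.assert_allclose(v.std(axis=1, ddof=1), 1.0, atol=1e-8)


def test_transform_matches_oracle():
    rng = np.random.default_rng(21)
    vals = rng.lognormal(10, 1, size=(4, 12))
    vals[rng.random(vals.shape) < 0.15] = np.nan
    batch = ["A"] * 6 + ["B"] * 6
    m, batches = _matrix(vals, batch=batch)
    res = log2_batch_center_autoscale(m, batches)
    # independent oracle recomputation
    L = np.log2(vals)
    for b in ("A", "B"):
        cols = np.array(batch) == b
        med = np.nanmedian(L[:, cols], axis=1)
        L[:, cols] -= med[:, None]
    mean = np.nanmean(L, axis=1)
    sd = np.nanstd(L, axis=1, ddof=1)
    Z = (L - mean[:, None]) / sd[:, None]
    np.testing.assert_allclose(res.values.to_numpy(), Z, atol=1e-10)
    np.testing.assert_allclose(res.sd.to_numpy(), sd, atol=1e-12)


def test_constant_feature_dropped():
    m, batches = _matrix(np.vstack([np.full(6, 7.0), np.arange(1.0, 7.0)]))
    res = log2_batch_center_autoscale(m, batches)
    assert res.dropped == ["f0"]
    assert list(res.values.index) == ["f1"]


def test_zero_replaced_by_half_minimum():
    m, batches = _matrix(np.array([[0.0, 4.0, 8.0, 16.0]]))
    res = log2_batch_center_autoscale(m, batches)
    # zero becomes 2.0 = half of min positive (4.0); check via reverse transform
    L = res.values.iloc[0].to_numpy() * res.sd.iloc[0] + res.mean.iloc[0]
    med = np.median(np.log2([2.0, 4.0, 8.0, 16.0]))
    assert L[0] + med == pytest.approx(1.0)  # log2(2.0)


def test_negative_intensity_raises():
    m, batches = _matrix(np.array([[1.0, -2.0, 3.0]]))
    with pytest.raises(ValueError, match="negative"):
        log2_batch_center_autoscale(m, batches)


# ---------------------------------------------------------------------------
# kNN imputation
# ---------------------------------------------------------------------------


def _scaled(rng, shape):
    X = rng.normal(size=shape)
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    return X


def test_knn_zero_distance_neighbor():
    rng = np.random.default_rng(2)
    X = _scaled(rng, (6, 10))
    X[1] = X[0]  # exact duplicate of feature 0
    df = pd.DataFrame(X.copy(), index=[f"f{i}" for i in range(6)])
    truth = X[0, 3]
    df.iloc[0, 3] = np.nan
    out = knn_impute(df, k=3)
    assert out.iloc[0, 3] == pytest.approx(truth)


def test_knn_clamps_k_to_candidates():
    rng = np.random.default_rng(3)
    X = _scaled(rng, (3, 8))
    df = pd.DataFrame(X, index=list("abc"))
    df.iloc[0, 0] = np.nan
    out = knn_impute(df, k=50)  # only 2 candidates exist
    d = {}
    for g in (1, 2):
        diff = X[0, 1:] - X[g, 1:]
        d[g] = np.sqrt((diff**2).mean())
    w = {g: 1 / d[g] for g in d}
    expected = sum(w[g] * X[g, 0] for g in w) / sum(w.values())
    assert out.iloc[0, 0] == pytest.approx(expected)


def test_knn_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    X = _scaled(rng, (20, 10))
    df = pd.DataFrame(X.copy(), index=[f"f{i}" for i in range(20)])
    mask = [(0, 1), (3, 4), (7, 9), (12, 0), (19, 5)]
    for f, s in mask:
        df.iloc[f, s] = np.nan
    out = knn_impute(df, k=4)
    M = ~df.isna().to_numpy()
    V = df.to_numpy()
    for f, s in mask:
        cands = []
        for g in range(20):
            if g == f or not M[g, s]:
                continue
            co = M[f] & M[g]
            if not co.any():
                continue
            dist = np.sqrt(((V[f, co] - V[g, co]) ** 2).sum() / co.sum())
            cands.append((dist, V[g, s]))
        cands.sort(key=lambda t: t[0])
        top = cands[:4]
        w = np.array([1 / d for d, _ in top])
        expected = float((w * np.array([v for _, v in top])).sum() / w.sum())
        assert out.iloc[f, s] == pytest.approx(expected, abs=1e-10)


def test_knn_preserves_observed_entries():
    rng = np.random.default_rng(23)
    X = _scaled(rng, (10, 8))
    df = pd.DataFrame(X.copy())
    df.iloc[2, 2] = np.nan
    out = knn_impute(df, k=3)
    obs = ~df.isna()
    np.testing.assert_array_equal(out.to_numpy()[obs.to_numpy()], df.to_numpy()[obs.to_numpy()])
    assert not out.isna().any().any()


def test_knn_no_candidates_falls_back_to_mean():
    df = pd.DataFrame([[np.nan, 1.0, -1.0]], index=["a"])  # single feature: no candidates
    with pytest.warns(UserWarning, match="no imputation candidates"):
        out = knn_impute(df, k=3)
    assert out.iloc[0, 0] == pytest.approx(np.nanmean([1.0, -1.0]))


def test_knn_beats_mean_imputation_on_synthetic(smoke_sim):
    """Masking 5% of observed entries: kNN RMSE < mean-imputation RMSE."""
    from mwaskit.qc import QcThresholds, apply_qc

    filtered, _ = apply_qc(smoke_sim.hilic, QcThresholds())
    summarized = summarize_replicates(filtered)
    res = log2_batch_center_autoscale(summarized, filtered.sample_batches)
    V = res.values.to_numpy()
    rng = np.random.default_rng(99)
    obs = np.argwhere(~np.isnan(V))
    pick = obs[rng.choice(len(obs), size=int(0.05 * len(obs)), replace=False)]
    masked = res.values.copy()
    truth = V[pick[:, 0], pick[:, 1]]
    masked.values[pick[:, 0], pick[:, 1]] = np.nan
    out = knn_impute(masked, k=10).to_numpy()
    knn_rmse = np.sqrt(np.mean((out[pick[:, 0], pick[:, 1]] - truth) ** 2))
    means = np.nanmean(masked.to_numpy(), axis=1)
    mean_rmse = np.sqrt(np.mean((means[pick[:, 0]] - truth) ** 2))
    assert knn_rmse < mean_rmse
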