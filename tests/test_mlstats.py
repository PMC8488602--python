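"""PCA conventions, clustering, MDS, LASSO/MPC and correlation analyses."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from conftest import planted_lasso_problem
from omicflux.mlstats import (
    correlation_distance,
    kmeans_cluster,
    lasso_mpc,
    nonmetric_mds,
    pathway_correlation,
    pathway_pca_aggregate,
    pc_flux_association,
    pca_fit,
    pearson_with_ci,
    silhouette_scan,
    top_k_predictors,
)
from omicflux.model import SubsystemIndex


def _rand_df(n, p, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        index=[f"c{i}" for i in range(n)],
        columns=[f"f{j}" for j in range(p)],
    )


# --- PCA -------------------------------------------------------------------


def test_pca_normalization_identities():
    df = _rand_df(10, 6)
    res = pca_fit(df)
    np.testing.assert_allclose(res.var_contrib.sum(axis=0), 100.0)
    np.testing.assert_allclose(res.ind_cos2.sum(axis=1), 1.0)
    assert res.eigenvalues.sum() == pytest.approx(6.0)


def test_pca_two_identical_columns_contribute_fifty_each():
    rng = np.random.default_rng(3)
    col = rng.normal(size=8)
    df = pd.DataFrame({"a": col, "b": col})
    res = pca_fit(df)
    np.testing.assert_allclose(res.var_contrib["Dim.1"], [50.0, 50.0])


def test_pca_reconstructs_standardized_matrix():
    df = _rand_df(9, 5, seed=1)
    res = pca_fit(df)
    Z = (df.to_numpy() - res.center) / res.scale
    recon = res.ind_coord.to_numpy() @ res.loadings.to_numpy().T
    np.testing.assert_allclose(recon, Z, atol=1e-8)


def test_pca_requires_two_rows():
    with pytest.raises(ValueError):
        pca_fit(_rand_df(1, 4))


def test_pca_constant_column_handled():
    df = _rand_df(8, 3, seed=2)
    df["const"] = 5.0
    res = pca_fit(df)
    assert (res.var_contrib.loc["const"] == 0).all()
    assert res.eigenvalues.sum() == pytest.approx(3.0)


def test_pathway_aggregation_sums_and_averages():
    index = SubsystemIndex(
        names=["A", "B"], membership=[[0, 1], [1]], cardinality=np.array([2, 1])
    )
    contrib = np.array([[10.0, 1.0], [20.0, 3.0]])
    table = pathway_pca_aggregate(contrib, index)
    assert table.loc["A", "PC1 Sum"] == 30.0
    assert table.loc["A", "PC1 Average"] == 15.0
    # reaction 1 belongs to both subsystems and is counted in each
    assert table.loc["B", "PC1 Sum"] == 20.0
    assert table.loc["B", "PC2 Average"] == 3.0


def test_pathway_aggregation_partitions_total_for_single_membership():
    rng = np.random.default_rng(5)
    contrib = rng.uniform(0, 10, size=(6, 2))
    index = SubsystemIndex(
        names=["A", "B"],
        membership=[[0, 1, 2], [3, 4, 5]],
        cardinality=np.array([3, 3]),
    )
    table = pathway_pca_aggregate(contrib, index)
    assert table["PC1 Sum"].sum() == pytest.approx(contrib[:, 0].sum())
    assert table["PC2 Sum"].sum() == pytest.approx(contrib[:, 1].sum())


def test_pc_flux_association_matches_normal_equations():
    rng = np.random.default_rng(7)
    x = rng.normal(size=12)
    y = 3.0 * x + 1.0 + 0.1 * rng.normal(size=12)
    r, slope, intercept = pc_flux_association(x, y)
    X = np.vstack([x, np.ones_like(x)]).T
    beta = np.linalg.solve(X.T @ X, X.T @ y)  # normal-equations oracle
    assert slope == pytest.approx(beta[0])
    assert intercept == pytest.approx(beta[1])
    assert r == pytest.approx(pearsonr(x, y).statistic)
    # exact linearity and degenerate input
    r1, *_ = pc_flux_association(x, 2 * x + 5)
    assert r1 == pytest.approx(1.0)
    rnan, *_ = pc_flux_association(x, np.full_like(x, 2.0))
    assert np.isnan(rnan)


# --- distances and clustering ----------------------------------------------


def test_correlation_distance_identical_and_anticorrelated_rows():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    X = np.vstack([base, base, -base])
    d = squareform(correlation_distance(X), checks=False)
    assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
    assert d[0, 2] == pytest.approx(2.0)


def test_correlation_distance_matches_pdist_oracle():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(5, 4))
    np.testing.assert_allclose(
        correlation_distance(X), pdist(X, metric="correlation"), atol=1e-12
    )


def test_correlation_distance_constant_row_gets_distance_one():
    X = np.vstack([np.ones(4), np.array([1.0, 2.0, 3.0, 4.0])])
    d = squareform(correlation_distance(X), checks=False)
    assert d[0, 1] == 1.0


def test_cityblock_distance_definition():
    labels, C = kmeans_cluster(np.array([[0.0, 0.0], [1.0, 2.0]]), k=2, seed=0)
    # with k = n each point is its own centroid; d((0,0),(1,2)) = 3 separates them
    assert len(set(labels)) == 2
    assert np.abs(np.array([0.0, 0.0]) - np.array([1.0, 2.0])).sum() == 3.0


def test_kmeans_recovers_planted_blobs():
    rng = np.random.default_rng(21)
    blob1 = rng.normal(0, 0.2, size=(15, 4))
    blob2 = rng.normal(5, 0.2, size=(15, 4))
    X = np.vstack([blob1, blob2])
    truth = np.array([0] * 15 + [1] * 15)
    labels, _ = kmeans_cluster(X, k=2, seed=0)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_kmeans_deterministic_under_fixed_seed():
    X = _rand_df(20, 5, seed=4).to_numpy()
    a, _ = kmeans_cluster(X, k=3, seed=42)
    b, _ = kmeans_cluster(X, k=3, seed=42)
    assert (a == b).all()


def test_kmeans_k_validation():
    X = np.ones((3, 2))
    with pytest.raises(ValueError):
        kmeans_cluster(X, k=5)
    with pytest.raises(ValueError):
        kmeans_cluster(X, k=1)


def test_silhouette_scan_finds_two_planted_groups():
    rng = np.random.default_rng(1)
    base1, base2 = rng.normal(size=10), rng.normal(size=10)
    X = np.array(
        [base1 + 0.1 * rng.normal(size=10) for _ in range(12)]
        + [base2 + 0.1 * rng.normal(size=10) for _ in range(12)]
    )
    scores, best_k = silhouette_scan(X, k_range=range(2, 8), seed=0)
    assert best_k == 2
    assert all(-1.0 <= s <= 1.0 for s in scores.values())


def test_silhouette_scan_skips_oversized_k():
    X = _rand_df(6, 4, seed=9).to_numpy()
    scores, _ = silhouette_scan(X, k_range=range(2, 31), seed=0)
    assert max(scores) <= 5


# --- MDS -------------------------------------------------------------------


def test_mds_embedding_shape_and_stress_reduction():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(10, 4))
    d = correlation_distance(X)
    Y, stress = nonmetric_mds(d, dims=2, seed=0)
    assert Y.shape == (10, 2)
    assert 0 <= stress < 1.0


def test_mds_handles_duplicate_points_via_retry():
    # duplicate rows give zero dissimilarity; the embedding must still return
    X = np.vstack([np.arange(4.0), np.arange(4.0), np.array([4.0, 1, 0, 2]),
                   np.array([0.0, 3, 1, 2])])
    d = pdist(X, metric="euclidean")
    Y, _ = nonmetric_mds(d, dims=2, seed=3)
    assert Y.shape == (4, 2)


def test_mds_rejects_malformed_input():
    with pytest.raises(ValueError):
        nonmetric_mds(np.array([1.0, 2.0]), dims=2)


# --- LASSO -----------------------------------------------------------------


def test_lasso_path_starts_all_zero_and_recovers_planted_signal():
    X, y = planted_lasso_problem(seed=0)
    res = lasso_mpc(pd.DataFrame(X), y)
    assert (res.coef_path.iloc[:, 0] == 0).all()  # largest penalty
    assert {0, 1, 2} <= set(res.retained.index)
    assert res.mpc[0] > 0 and res.mpc[1] < 0 and res.mpc[2] > 0
    # retained is sorted by MPC descending and obeys the cutoff
    vals = res.retained["mpc"].to_numpy()
    assert (np.diff(vals) <= 0).all()
    assert (np.abs(vals) > 0.01).all()


def test_lasso_nonzero_only_averaging_mode():
    X, y = planted_lasso_problem(seed=1)
    res_all = lasso_mpc(pd.DataFrame(X), y)
    res_nz = lasso_mpc(pd.DataFrame(X), y, nonzero_only=True)
    # averaging only over nonzero path entries can only grow the magnitude
    assert abs(res_nz.mpc[0]) >= abs(res_all.mpc[0])


def test_lasso_input_validation():
    with pytest.raises(ValueError):
        lasso_mpc(np.ones((1, 3)), [1.0])
    with pytest.raises(ValueError):
        lasso_mpc(np.ones((4, 3)), [1.0, 2.0])


# --- correlation -----------------------------------------------------------


def test_pearson_with_ci_matches_textbook_oracle():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(12, 6))
    y = rng.normal(size=12)
    res = pearson_with_ci(pd.DataFrame(X), y)
    n = 12
    for j in range(6):
        r_o, p_o = pearsonr(X[:, j], y)
        row = res.table.iloc[j]
        assert row["r"] == pytest.approx(r_o)
        assert row["pval"] == pytest.approx(p_o)
        z = np.arctanh(r_o)
        assert row["lb95"] == pytest.approx(np.tanh(z - 1.96 / np.sqrt(n - 3)))
        assert row["ub95"] == pytest.approx(np.tanh(z + 1.96 / np.sqrt(n - 3)))
        assert row["lb95"] <= row["r"] <= row["ub95"]


def test_pearson_perfect_and_constant_columns():
    y = np.arange(8.0)
    X = pd.DataFrame({"prop": 2 * y, "const": np.full(8, 3.0)})
    res = pearson_with_ci(X, y)
    assert res.table.loc["prop", "r"] == pytest.approx(1.0)
    assert res.table.loc["prop", "pval"] == 0.0
    assert res.table.loc["const"].isna().all()


def test_pearson_p_value_close_to_exhaustive_permutation_null():
    """The t-based p-value approximates the exact permutation null at n=6."""
    from itertools import permutations

    for seed in range(5):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = 0.8 * x + rng.normal(size=6)
        p_t = pearson_with_ci(x.reshape(-1, 1), y).table["pval"].iloc[0]
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        hits = sum(
            abs(np.corrcoef(x[list(p)], y)[0, 1]) >= r_obs - 1e-12
            for p in permutations(range(6))
        )
        p_perm = hits / 720
        assert p_t == pytest.approx(p_perm, abs=0.1)


def test_top_k_predictors_selection_and_clamping():
    tab = pd.DataFrame(
        {
            "r": [0.9, -0.8, 0.5, np.nan, -0.2],
            "pval": 0.1,
            "lb95": 0.0,
            "ub95": 0.0,
        },
        index=["a", "b", "c", "d", "e"],
    )
    from omicflux.mlstats import CorrResult

    pos, neg = top_k_predictors(CorrResult(tab), k=10)
    assert list(pos.index) == ["a", "c", "e", "b"]  # NaN excluded, clamped to 4
    assert list(neg.index) == ["b", "e", "c", "a"]
    pos2, _ = top_k_predictors(CorrResult(tab), k=2)
    assert list(pos2.index) == ["a", "c"]


def test_pathway_correlation_bins_and_mean_abs():
    index = SubsystemIndex(
        names=["S1", "S2"], membership=[[0, 1], [2, 3, 4]],
        cardinality=np.array([2, 3]),
    )
    tab = pd.DataFrame(
        {
            "r": [-0.4, 0.6, 0.5, np.nan, 0.95],
            "pval": np.nan, "lb95": np.nan, "ub95": np.nan,
        },
        index=[f"R{i}" for i in range(5)],
    )
    from omicflux.mlstats import CorrResult

    mean_df, bins_df = pathway_correlation(CorrResult(tab), index)
    assert mean_df.loc["S1", "mean_abs_r"] == pytest.approx(0.5)  # (0.4+0.6)/2
    # NaN treated as 0 in the mean
    assert mean_df.loc["S2", "mean_abs_r"] == pytest.approx((0.5 + 0.0 + 0.95) / 3)
    assert bins_df.loc["S1", "[-0.5, -0.3)"] == 1
    assert bins_df.loc["S1", "[0.5, 0.7)"] == 1  # r = 0.6
    assert bins_df.loc["S2", "[0.5, 0.7)"] == 1  # r = 0.5 falls in [0.5, 0.7)
    assert bins_df.loc["S2", "[-0.1, 0.1)"] == 1  # NaN -> 0
    assert bins_df.loc["S2", "overflow"] == 1  # r = 0.95
    # bin counts (excluding overflow) sum to members with r in [-0.7, 0.7)
    in_range = bins_df.drop(columns="overflow").sum(axis=1)
    assert in_range["S1"] == 2 and in_range["S2"] == 2
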