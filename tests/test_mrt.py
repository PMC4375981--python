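"""Tests for PCA preprocessing and the multivariate regression tree."""

import numpy as np
import pandas as pd
import pytest

from _oracles import exhaustive_depth2_ss, naive_greedy_tree_ss
from gardenqg import mrt
from gardenqg.mrt import (
    ResponseMatrix,
    fit_mrt,
    leaf_profiles,
    pca_growth,
    select_max_leaves_cv,
    surrogate_equivalent_splits,
)


class TestPca:
    def test_rank_one_data_fully_explained_by_pc1(self):
        t = np.linspace(0, 1, 30)
        df = pd.DataFrame({f"c{i}": (i + 1) * t for i in range(8)})
        res = pca_growth(df, n_components=2, scale=False)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_rotation_invariance_of_spectrum(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((60, 8)) @ np.diag(np.arange(1, 9))
        q, _ = np.linalg.qr(rng.standard_normal((8, 8)))
        a = pca_growth(pd.DataFrame(X), scale=False).variance_fractions
        b = pca_growth(pd.DataFrame(X @ q), scale=False).variance_fractions
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_fractions_match_eigen_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 8)) * rng.uniform(0.5, 3.0, 8)
        df = pd.DataFrame(X)
        res = pca_growth(df, n_components=2, scale=True)
        Z = (df - df.mean()) / df.std(ddof=1)
        eig = np.sort(np.linalg.eigvalsh(np.cov(Z.to_numpy().T)))[::-1]
        np.testing.assert_allclose(
            res.variance_fractions, eig[:2] / eig.sum(), atol=1e-10
        )

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.standard_normal((20, 3)), columns=["a", "b", "c"])
        df["const"] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            res = pca_growth(df, n_components=2)
        assert "const" not in res.loadings.index


class TestFitMrt:
    def test_perfectly_separable_single_column(self):
        resp = pd.DataFrame({"y": [0.0, 0.0, 10.0, 10.0]})
        pred = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        tree = fit_mrt(resp, pred, max_leaves=2, min_node_size=1)
        assert tree.root.split_var == "x"
        assert tree.root.split_threshold == pytest.approx(2.5)
        assert tree.variance_explained == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(12, 51))
        Y = rng.standard_normal((n, int(rng.integers(1, 4))))
        X = rng.standard_normal((n, int(rng.integers(1, 4))))
        resp = pd.DataFrame(Y)
        pred = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
        tree = fit_mrt(resp, pred, max_leaves=4, min_node_size=3, max_depth=2,
                       standardize=False)
        greedy_ss = sum(leaf.ss for leaf in tree.leaves())
        naive_ss = naive_greedy_tree_ss(Y, X, 3, 4, 2)
        assert greedy_ss == pytest.approx(naive_ss, abs=1e-9)
        # greedy can never beat the exhaustive depth-2 optimum
        assert greedy_ss >= exhaustive_depth2_ss(Y, X, 3) - 1e-9

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        resp = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
        pred = pd.DataFrame(rng.standard_normal((40, 2)), columns=["x", "z"])
        t1 = fit_mrt(resp, pred, max_leaves=4, min_node_size=4)
        perm = rng.permutation(40)
        t2 = fit_mrt(resp.iloc[perm], pred.iloc[perm], max_leaves=4, min_node_size=4)
        assert t1.variance_explained == pytest.approx(t2.variance_explained, abs=1e-10)
        assert t1.root.split_var == t2.root.split_var
        assert t1.root.split_threshold == pytest.approx(t2.root.split_threshold)

    def test_monotone_predictor_transform_preserves_partition(self):
        rng = np.random.default_rng(4)
        resp = pd.DataFrame(rng.standard_normal((40, 2)))
        pred = pd.DataFrame({"x": rng.uniform(1, 5, 40)})
        t1 = fit_mrt(resp, pred, max_leaves=3, min_node_size=4)
        t2 = fit_mrt(resp, np.exp(pred), max_leaves=3, min_node_size=4)
        pd.testing.assert_series_equal(t1.leaf_membership(), t2.leaf_membership())
        assert t1.variance_explained == pytest.approx(t2.variance_explained, abs=1e-10)

    def test_variance_explained_monotone_in_max_leaves(self):
        rng = np.random.default_rng(5)
        resp = pd.DataFrame(rng.standard_normal((60, 3)))
        pred = pd.DataFrame(rng.standard_normal((60, 3)), columns=["a", "b", "c"])
        ve = [
            fit_mrt(resp, pred, max_leaves=k, min_node_size=5).variance_explained
            for k in range(1, 7)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(ve, ve[1:]))

    def test_standardized_columns_contribute_equally_at_root(self):
        rng = np.random.default_rng(6)
        resp = pd.DataFrame({"small": rng.normal(0, 0.1, 30), "big": rng.normal(0, 100, 30)})
        pred = pd.DataFrame({"x": rng.standard_normal(30)})
        tree = fit_mrt(resp, pred, max_leaves=1)
        # each z-scored column has root SS = n - 1
        assert tree.total_ss == pytest.approx(2 * 29, rel=1e-10)

    def test_constant_predictors_make_leaf(self):
        resp = pd.DataFrame({"y": [0.0, 1.0, 2.0, 3.0]})
        pred = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0]})
        tree = fit_mrt(resp, pred, max_leaves=3, min_node_size=1)
        assert tree.n_leaves == 1


class TestSurrogates:
    def test_duplicated_predictor_reported_everywhere(self):
        rng = np.random.default_rng(7)
        resp = pd.DataFrame(rng.standard_normal((30, 2)))
        x = rng.standard_normal(30)
        pred = pd.DataFrame({"x": x, "x_copy": x})
        tree = fit_mrt(resp, pred, max_leaves=3, min_node_size=3)
        equiv = surrogate_equivalent_splits(tree, resp, pred)
        for node in tree.internal_nodes():
            names = {v for v, _ in equiv[node.node_id]}
            assert {"x", "x_copy"} <= names

    def test_collinear_predictors_equivalent(self):
        rng = np.random.default_rng(8)
        resp = pd.DataFrame(rng.standard_normal((30, 1)))
        x = rng.standard_normal(30)
        pred = pd.DataFrame({"x": x, "x_lin": 3.0 * x + 2.0})
        tree = fit_mrt(resp, pred, max_leaves=2, min_node_size=3)
        equiv = surrogate_equivalent_splits(tree, resp, pred)
        names = {v for v, _ in equiv[tree.root.node_id]}
        assert names == {"x", "x_lin"}

    def test_matches_brute_force_rescan(self):
        rng = np.random.default_rng(9)
        Y = rng.standard_normal((25, 2))
        X = rng.standard_normal((25, 2))
        resp, pred = pd.DataFrame(Y), pd.DataFrame(X, columns=["a", "b"])
        tree = fit_mrt(resp, pred, max_leaves=2, min_node_size=3, standardize=False)
        equiv = surrogate_equivalent_splits(tree, resp, pred)
        root = tree.root
        best_gain = root.ss - root.left.ss - root.right.ss
        # brute force: every candidate achieving the same reduction
        expected = []
        for col in ["a", "b"]:
            xs = np.sort(pred[col].unique())
            for lo, hi in zip(xs[:-1], xs[1:]):
                thr = (lo + hi) / 2
                mask = pred[col].to_numpy() < thr
                gain = root.ss - (
                    ((Y[mask] - Y[mask].mean(0)) ** 2).sum()
                    + ((Y[~mask] - Y[~mask].mean(0)) ** 2).sum()
                )
                if abs(gain - best_gain) <= 1e-9 * max(1, abs(best_gain)):
                    expected.append((col, thr))
        assert sorted(equiv[root.node_id]) == sorted(
            (c, pytest.approx(t)) for c, t in expected
        )


class TestLeafProfiles:
    def test_single_leaf_profile_is_grand_mean(self):
        rng = np.random.default_rng(10)
        resp = pd.DataFrame(rng.standard_normal((20, 2)), columns=["a", "b"])
        pred = pd.DataFrame({"x": np.ones(20)})
        tree = fit_mrt(resp, pred, max_leaves=3)
        prof = leaf_profiles(tree, resp)
        assert prof["mean"].tolist() == pytest.approx(
            [resp["a"].mean(), resp["b"].mean()]
        )
        np.testing.assert_allclose(prof["deviation_sd"], 0.0, atol=1e-12)

    def test_two_leaf_perfect_split_means(self):
        resp = pd.DataFrame({"y": [0.0, 0.0, 10.0, 10.0]})
        pred = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        tree = fit_mrt(resp, pred, max_leaves=2, min_node_size=1)
        prof = leaf_profiles(tree, resp).sort_values("mean")
        assert prof["mean"].tolist() == [0.0, 10.0]

    def test_planted_group_structure_recovered(self):
        rng = np.random.default_rng(11)
        centers = np.array([[0, 0], [5, 0], [0, 5], [5, 5], [10, 10]], float)
        rows, xs = [], []
        for g, c in enumerate(centers):
            rows.append(c + rng.normal(0, 0.2, (12, 2)))
            xs.append(np.full(12, g) + rng.uniform(-0.2, 0.2, 12))
        resp = pd.DataFrame(np.vstack(rows), columns=["a", "b"])
        pred = pd.DataFrame({"x": np.concatenate(xs)})
        tree = fit_mrt(resp, pred, max_leaves=5, min_node_size=5)
        prof = leaf_profiles(tree, resp)
        means = prof.pivot(index="leaf", columns="trait", values="mean")[["a", "b"]]
        found = means.to_numpy()
        assert len(found) == 5
        # one-to-one nearest matching between leaf means and planted centers
        dist = np.linalg.norm(found[:, None, :] - centers[None, :, :], axis=2)
        assignment = dist.argmin(axis=1)
        assert sorted(assignment) == [0, 1, 2, 3, 4]
        assert dist[np.arange(5), assignment].max() < 0.3


def test_cv_size_selection_prefers_true_structure():
    """CV picks a size near the planted 3-group structure, not the maximum."""
    rng = np.random.default_rng(12)
    groups = np.repeat([0, 1, 2], 30)
    resp = pd.DataFrame({"y": groups * 5.0 + rng.normal(0, 0.5, 90)})
    pred = pd.DataFrame({"x": groups + rng.uniform(-0.3, 0.3, 90)})
    best, table = select_max_leaves_cv(
        resp, pred, candidate_leaves=[2, 3, 4, 5, 6], k_folds=5, seed=0
    )
    assert best == 3
    assert len(table) == 5
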