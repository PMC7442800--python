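"""Association testing (spline F-test + BH), profile smoothing, pattern
clustering, branch comparison and lasso TF activity."""

import numpy as np
import pandas as pd
import pytest

import treefates as tf
from treefates.trajstats import FittedProfiles, ProfileGrid, bh_adjust


def brute_force_bh(p):
    """Independent oracle: q_i = min_{j >= i} p_(j) * m / j on sorted p."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestBHAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(3, 200))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-15)


def _assoc_data(rng, n_cells=120):
    pt = np.sort(rng.uniform(0, 10, n_cells))
    flat = np.full(n_cells, 2.0) + rng.normal(0, 1e-3, n_cells)
    ramp = 0.2 * pt + rng.normal(0, 0.05, n_cells)  # amplitude 2
    noise = rng.normal(0, 0.5, n_cells)
    expr = np.vstack([flat, ramp, noise])
    return expr, np.array(["flat", "ramp", "noise"], dtype=object), pt


class TestAssociatedGenes:
    def test_flat_gene_not_associated_ramp_is(self, rng):
        expr, genes, pt = _assoc_data(rng)
        res = tf.test_associated_genes(expr, genes, pt)
        tab = res.table.set_index("gene_id")
        assert not tab.loc["flat", "associated"]
        assert tab.loc["ramp", "associated"]
        assert tab.loc["ramp", "q_value"] < 1e-10
        assert tab.loc["ramp", "amplitude"] == pytest.approx(2.0, abs=0.1)

    def test_qvalues_dominate_pvalues(self, rng):
        expr, genes, pt = _assoc_data(rng)
        tab = tf.test_associated_genes(expr, genes, pt).table
        assert (tab["q_value"] >= tab["p_value"] - 1e-15).all()

    def test_amplitude_gate(self, rng):
        pt = np.sort(rng.uniform(0, 10, 100))
        small = 0.02 * pt + rng.normal(0, 0.01, 100)  # significant but amplitude 0.2
        expr = np.vstack([small, rng.normal(0, 1, 100)])
        tab = tf.test_associated_genes(expr, np.array(["small", "x"], dtype=object), pt,
                                       a_min=0.5).table.set_index("gene_id")
        assert tab.loc["small", "q_value"] < 0.05
        assert not tab.loc["small", "associated"]

    def test_too_few_cells_errors(self, rng):
        with pytest.raises(ValueError):
            tf.test_associated_genes(np.zeros((2, 10)), np.array(["a", "b"]), np.arange(10))

    def test_type_i_error_controlled(self, rng):
        """Pure-noise genes: called fraction at alpha=0.05 stays near alpha."""
        pt = np.sort(rng.uniform(0, 10, 150))
        expr = rng.normal(0, 1, size=(300, 150))
        tab = tf.test_associated_genes(expr, np.array([f"g{i}" for i in range(300)], dtype=object),
                                       pt, a_min=0.0).table
        assert tab["associated"].mean() <= 0.07


class TestFitProfiles:
    def test_noiseless_linear_recovered(self):
        pt = np.linspace(0, 10, 80)
        expr = (0.5 * pt)[None, :]
        prof = tf.fit_gene_profiles(expr, np.array(["g"], dtype=object), pt).single()
        interior = (prof.grid > 1) & (prof.grid < 9)
        np.testing.assert_allclose(prof.values[0][interior], 0.5 * prof.grid[interior], atol=1e-3)

    def test_large_gamma_limit_is_least_squares_line(self, rng):
        """The second-derivative penalty shrinks toward the OLS line; for
        slope-free data that line is the constant mean."""
        pt = np.linspace(0, 10, 60)
        y = np.sin(pt * 2) + rng.normal(0, 0.1, 60)
        expr = y[None, :]
        prof = tf.fit_gene_profiles(expr, np.array(["g"], dtype=object), pt, gamma=1e9).single()
        slope, intercept = np.polyfit(pt, y, 1)
        np.testing.assert_allclose(prof.values[0], slope * prof.grid + intercept, atol=1e-3)

    def test_no_overshoot_on_monotone_data(self, rng):
        pt = np.linspace(0, 10, 100)
        y = 1 / (1 + np.exp(-(pt - 5))) + rng.normal(0, 0.02, 100)
        prof = tf.fit_gene_profiles(y[None, :], np.array(["g"], dtype=object), pt, gamma=5).single()
        assert prof.values[0].max() <= y.max() + 1e-6

    def test_tiny_path_marked_unavailable(self):
        pt = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        expr = np.ones((1, 5))
        with pytest.warns(UserWarning, match="fewer than 4"):
            prof = tf.fit_gene_profiles(expr, np.array(["g"], dtype=object), pt,
                                        paths={"p": np.array([0, 1, 2])})
        assert np.isnan(prof.by_path["p"].values).all()


class TestClusterProfiles:
    def _profiles(self, mat, genes):
        grid = np.linspace(0, 1, mat.shape[1])
        return FittedProfiles(np.asarray(genes, dtype=object), {"p": ProfileGrid(grid, mat)})

    def test_two_identical_groups_exact_partition(self):
        up = np.linspace(0, 1, 50)
        mat = np.vstack([np.tile(up, (4, 1)), np.tile(up[::-1], (4, 1))])
        got = tf.cluster_profiles(self._profiles(mat, [f"g{i}" for i in range(8)]), n_patterns=2)
        lab = got.labels
        assert len(set(lab[:4])) == 1 and len(set(lab[4:])) == 1
        assert lab.iloc[0] != lab.iloc[-1]

    def test_singletons_when_k_equals_n(self, rng):
        mat = rng.normal(size=(6, 30))
        got = tf.cluster_profiles(self._profiles(mat, [f"g{i}" for i in range(6)]), n_patterns=6)
        assert got.labels.nunique() == 6

    def test_thirty_nonempty_patterns(self, rng):
        mat = rng.normal(size=(90, 40))
        got = tf.cluster_profiles(self._profiles(mat, [f"g{i}" for i in range(90)]), n_patterns=30)
        assert got.labels.nunique() == 30

    def test_order_invariance_up_to_relabeling(self, rng):
        mat = np.vstack([np.tile(np.linspace(0, 1, 30), (5, 1)) + rng.normal(0, 0.01, (5, 30)),
                         np.tile(np.linspace(1, 0, 30), (5, 1)) + rng.normal(0, 0.01, (5, 30))])
        genes = [f"g{i}" for i in range(10)]
        a = tf.cluster_profiles(self._profiles(mat, genes), n_patterns=2).labels
        perm = rng.permutation(10)
        b = tf.cluster_profiles(self._profiles(mat[perm], [genes[i] for i in perm]), n_patterns=2).labels
        b = b.reindex(a.index)
        # same partition: co-membership matrices agree
        same_a = a.to_numpy()[:, None] == a.to_numpy()[None, :]
        same_b = b.to_numpy()[:, None] == b.to_numpy()[None, :]
        np.testing.assert_array_equal(same_a, same_b)

    def test_too_many_patterns_errors(self, rng):
        mat = rng.normal(size=(5, 20))
        with pytest.raises(ValueError):
            tf.cluster_profiles(self._profiles(mat, [f"g{i}" for i in range(5)]), n_patterns=6)


def _profiles_for(genes, grid, fn):
    vals = np.vstack([fn(g, grid) for g in genes])
    return FittedProfiles(np.asarray(genes, dtype=object), {"p": ProfileGrid(grid, vals)})


class TestCompareBranches:
    def _skeletons(self):
        # two straight branches crossing at (1, 0)
        ta = np.linspace(0, 2, 10)
        a = np.column_stack([ta, ta - 1])
        b = np.column_stack([ta, 1 - ta])
        return (a, ta), (b, ta)

    def test_common_point_at_crossing(self):
        grid = np.linspace(0, 2, 100)
        prof = _profiles_for(["g1"], grid, lambda g, t: t)
        sk_a, sk_b = self._skeletons()
        cmp = tf.compare_branches({"g1"}, {"g1"}, prof, prof, sk_a, sk_b, n_samples=400)
        assert cmp.common_point_a[0] == pytest.approx(1.0, abs=0.02)
        np.testing.assert_allclose(cmp.common_point_a[1], [1.0, 0.0], atol=0.02)

    def test_identical_sets_no_specific(self):
        grid = np.linspace(0, 2, 100)
        prof = _profiles_for(["g1", "g2"], grid, lambda g, t: t)
        sk_a, sk_b = self._skeletons()
        cmp = tf.compare_branches({"g1", "g2"}, {"g1", "g2"}, prof, prof, sk_a, sk_b)
        assert cmp.branch_specific == {}
        assert cmp.common_genes == {"g1", "g2"}

    def test_b_only_gene_assigned_to_b(self):
        grid = np.linspace(0, 2, 100)
        prof = _profiles_for(["g1", "g2"], grid, lambda g, t: t)
        sk_a, sk_b = self._skeletons()
        cmp = tf.compare_branches({"g1"}, {"g1", "g2"}, prof, prof, sk_a, sk_b)
        assert cmp.branch_specific == {"g2": "B"}

    def test_early_late_split(self):
        grid = np.linspace(0, 2, 120)
        def fn(g, t):
            t_on = 1.2 if g.startswith("early") else 1.8
            return 1 / (1 + np.exp(-12 * (t - t_on)))
        genes = ["early1", "early2", "early3", "late1", "late2", "late3"]
        prof = _profiles_for(genes, grid, fn)
        sk_a, sk_b = self._skeletons()
        cmp = tf.compare_branches(set(genes), set(genes), prof, prof, sk_a, sk_b)
        assert all(cmp.early_late[g] == "early" for g in genes[:3])
        assert all(cmp.early_late[g] == "late" for g in genes[3:])

    def test_empty_set_errors(self):
        grid = np.linspace(0, 2, 50)
        prof = _profiles_for(["g1"], grid, lambda g, t: t)
        sk_a, sk_b = self._skeletons()
        with pytest.raises(ValueError):
            tf.compare_branches(set(), {"g1"}, prof, prof, sk_a, sk_b)


def test_synthetic_target_matrix_layout(rng):
    genes = [f"g{i}" for i in range(30)]
    m, tf_ids = tf.synthetic_target_matrix(
        genes, {"tfA": ["g0", "g1", "g2"]}, n_decoy_tfs=2, decoy_size=5, seed=1
    )
    assert m.shape == (30, 3) and tf_ids == ["tfA", "decoy_0", "decoy_1"]
    assert m[:3, 0].sum() == 3 and m[:, 0].sum() == 3
    assert m[:, 1].sum() == 5 and m[:, 2].sum() == 5


class TestTFActivity:
    def test_identifiable_module(self, rng):
        grid = np.linspace(0, 1, 60)
        signal = np.sin(2 * np.pi * grid)
        n_genes = 40
        targets = np.zeros((n_genes, 2))
        targets[:15, 0] = 1  # true TF drives genes 0..14
        targets[rng.choice(n_genes, 10, replace=False), 1] = 1  # decoy random targets
        vals = np.where(targets[:, [0]] > 0, signal[None, :], rng.normal(0, 0.01, (n_genes, 60)))
        prof = FittedProfiles(np.array([f"g{i}" for i in range(n_genes)], dtype=object),
                              {"p": ProfileGrid(grid, vals)})
        act = tf.infer_tf_activity(prof, targets, ["real", "decoy"], alpha=0.5)
        corr = np.corrcoef(act.activities[0], signal)[0, 1]
        assert corr > 0.95
        assert np.abs(act.activities[1]).max() < 0.1 * np.abs(act.activities[0]).max()

    def test_huge_alpha_all_zero(self, rng):
        grid = np.linspace(0, 1, 20)
        vals = rng.normal(size=(10, 20))
        prof = FittedProfiles(np.array([f"g{i}" for i in range(10)], dtype=object),
                              {"p": ProfileGrid(grid, vals)})
        m = (rng.random((10, 3)) < 0.4).astype(float)
        m[0, 0] = 1
        act = tf.infer_tf_activity(prof, m, ["a", "b", "c"], alpha=1e9)
        np.testing.assert_allclose(act.activities, 0.0)

    def test_alpha_zero_is_least_squares(self, rng):
        grid = np.linspace(0, 1, 15)
        vals = rng.normal(size=(3, 15))
        prof = FittedProfiles(np.array(["g0", "g1", "g2"], dtype=object),
                              {"p": ProfileGrid(grid, vals)})
        m = np.array([[1.0, 0.0, 1.0], [0.0, 1.0, 1.0], [1.0, 1.0, 0.0]])
        act = tf.infer_tf_activity(prof, m, ["a", "b", "c"], alpha=0.0)
        y = vals - vals.mean(axis=1, keepdims=True)
        expected = np.linalg.solve(m, y)
        np.testing.assert_allclose(act.activities, expected, atol=1e-8)

    def test_zero_matrix_errors(self, rng):
        grid = np.linspace(0, 1, 10)
        prof = FittedProfiles(np.array(["g"], dtype=object),
                              {"p": ProfileGrid(grid, np.zeros((1, 10)))})
        with pytest.raises(ValueError):
            tf.infer_tf_activity(prof, np.zeros((1, 2)), ["a", "b"], alpha=1.0)
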