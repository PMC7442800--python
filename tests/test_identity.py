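"""Bootstrap heterogeneity curves, identity-gene tracing, endpoint markers."""

import numpy as np
import pandas as pd
import pytest

import treefates as tf


class TestBootstrapCurve:
    def test_identical_top_sets_plateau(self, rng):
        # every cell shares the same 100 most-expressed genes
        base = np.zeros((300, 20), dtype=int)
        base[:100] = rng.integers(50, 100, size=(100, 20))
        curve = tf.bootstrap_gene_accumulation(base, n_draws=50, top_k=100, n_reps=20, seed=1)
        np.testing.assert_array_equal(curve.mean_unique, 100.0)
        np.testing.assert_array_equal(curve.sd_unique, 0.0)

    def test_saturates_at_gene_count(self, rng):
        counts = rng.integers(1, 10, size=(60, 15))
        curve = tf.bootstrap_gene_accumulation(counts, n_draws=30, top_k=100, n_reps=10, seed=2)
        assert curve.mean_unique[-1] <= 60
        assert curve.top_k == 60

    def test_disjoint_top_sets_expectation(self):
        """Two cells with disjoint top-100 sets: after 2 draws with
        replacement the expected union is 100 * (1 + 1/2) = 150."""
        counts = np.zeros((200, 2), dtype=int)
        counts[:100, 0] = 10
        counts[100:, 1] = 10
        curve = tf.bootstrap_gene_accumulation(counts, n_draws=2, top_k=100, n_reps=1000, seed=3)
        sd_of_mean = curve.per_rep[:, 1].std() / np.sqrt(curve.n_reps)
        assert abs(curve.mean_unique[1] - 150.0) <= 3 * max(sd_of_mean, 1e-9)

    def test_every_repetition_monotone(self, rng):
        counts = rng.integers(0, 30, size=(500, 40))
        curve = tf.bootstrap_gene_accumulation(counts, n_draws=60, top_k=100, n_reps=25, seed=4)
        assert np.all(np.diff(curve.per_rep, axis=1) >= 0)

    def test_seeded(self, rng):
        counts = rng.integers(0, 30, size=(100, 10))
        a = tf.bootstrap_gene_accumulation(counts, seed=9)
        b = tf.bootstrap_gene_accumulation(counts, seed=9)
        np.testing.assert_array_equal(a.per_rep, b.per_rep)

    def test_empty_population_errors(self, rng):
        with pytest.raises(ValueError):
            tf.bootstrap_gene_accumulation(np.zeros((5, 4), dtype=int), cell_indices=np.array([], dtype=int))


def _identity_fixture(rng, n_cells=300):
    """Two trajectories sharing a root pool (pt 0..12); constructed genes:
    ubiquitous early, late-only, high-but-spotty, early-but-one-trajectory."""
    pt = np.sort(rng.uniform(0, 12, n_cells))
    half = rng.random(n_cells) < 0.5
    trajA = np.flatnonzero((pt <= 6) | half)
    trajB = np.flatnonzero((pt <= 6) | ~half)

    def sigmoid(t_on):
        return 4 / (1 + np.exp(-2 * (pt - t_on)))

    ubiq = sigmoid(2.0)
    late = sigmoid(9.0)
    spotty = sigmoid(2.0)
    a_only = sigmoid(2.0).copy()
    onB = np.zeros(n_cells, dtype=bool)
    onB[trajB] = True
    a_only[onB & (pt > 6)] = 0.0
    expr = np.vstack([ubiq, late, spotty, a_only])
    counts = np.rint(np.expm1(expr)).astype(int)
    counts[2] = np.where(rng.random(n_cells) < 0.10, 0, counts[2])  # 90% presence
    expr = np.log1p(counts)
    genes = np.array(["ubiq", "late", "spotty", "a_only"], dtype=object)
    return counts, expr, genes, pt, {"A": trajA, "B": trajB}


class TestTraceIdentity:
    def test_constructed_membership(self, rng):
        counts, expr, genes, pt, trajs = _identity_fixture(rng)
        got = tf.trace_identity_genes(counts, expr, genes, pt, trajs, t0=6.0, presence=0.98)
        assert got.gene_ids == ["ubiq"]
        assert got.presence_fractions.loc["ubiq"].min() > 0.98
        assert got.activation_times["ubiq"] < 6.0

    def test_presence_rule_excludes_95_percent_gene(self, rng):
        counts, expr, genes, pt, trajs = _identity_fixture(rng)
        got = tf.trace_identity_genes(counts, expr, genes, pt, trajs, t0=6.0, presence=0.98)
        assert "spotty" not in got.gene_ids

    def test_threshold_monotonicity(self, rng):
        counts, expr, genes, pt, trajs = _identity_fixture(rng)
        base = set(tf.trace_identity_genes(counts, expr, genes, pt, trajs, t0=6.0, presence=0.9).gene_ids)
        stricter_presence = set(
            tf.trace_identity_genes(counts, expr, genes, pt, trajs, t0=6.0, presence=0.99).gene_ids
        )
        lower_t0 = set(tf.trace_identity_genes(counts, expr, genes, pt, trajs, t0=4.0, presence=0.9).gene_ids)
        assert stricter_presence <= base
        assert lower_t0 <= base

    def test_no_cells_beyond_t0_errors(self, rng):
        counts, expr, genes, pt, trajs = _identity_fixture(rng)
        with pytest.raises(ValueError, match="beyond"):
            tf.trace_identity_genes(counts, expr, genes, pt, trajs, t0=50.0)

    def test_simulator_ground_truth_recovery(self):
        """Identity genes constructed by the generator are recovered exactly
        against branch-restricted module genes and flat noise genes."""
        ds = tf.simulate_dataset(tf.default_config(seed=33))
        expr = tf.normalize_counts(ds.counts)
        counts = ds.counts.subset_genes(~ds.counts.is_spikein)
        pt = ds.truth.true_pseudotime
        segs = ds.truth.true_segment
        trajs = {
            "A1": np.flatnonzero(np.isin(segs, ["trunk", "branchA", "branchA1"])),
            "A2": np.flatnonzero(np.isin(segs, ["trunk", "branchA", "branchA2"])),
            "B": np.flatnonzero(np.isin(segs, ["trunk", "branchB"])),
        }
        got = tf.trace_identity_genes(counts.dense(), expr.values, expr.gene_ids, pt, trajs,
                                      t0=6.0, presence=0.98)
        assert set(got.gene_ids) == ds.truth.identity_gene_ids


def _marker_fixture():
    """Two clusters, 10 genes: 5 built to pass both marker rules for cluster
    a, 5 built to fail one rule each way."""
    rng = np.random.default_rng(5)
    n_a, n_b = 30, 30
    rows, names = [], []
    for i in range(5):  # pass: high fold change, expressed everywhere in a
        rows.append(np.r_[rng.uniform(2.5, 3.0, n_a), rng.uniform(0.0, 0.2, n_b)])
        names.append(f"pass{i}")
    for i in range(3):  # fail fold change: equal in both clusters
        rows.append(np.r_[rng.uniform(1.0, 1.5, n_a), rng.uniform(1.0, 1.5, n_b)])
        names.append(f"flat{i}")
    for i in range(2):  # fail fraction: strong but expressed in <90% of a
        v = np.r_[rng.uniform(2.5, 3.0, n_a), np.zeros(n_b)]
        v[: n_a // 2] = 0.0
        rows.append(v)
        names.append(f"sparse{i}")
    expr = np.vstack(rows)
    labels = np.array(["a"] * n_a + ["b"] * n_b)
    return expr, np.array(names, dtype=object), labels


class TestEndpointMarkers:
    def test_constructed_fixture_counts(self):
        expr, genes, labels = _marker_fixture()
        tab = tf.endpoint_markers(expr, genes, labels)
        mk = tab[(tab["cluster"] == "a") & tab["is_marker"]]
        assert sorted(mk["gene_id"]) == [f"pass{i}" for i in range(5)]

    def test_exact_log2fc_boundary_excluded(self):
        # log2fc exactly 1.0: mean_in + eps = 2 * (mean_out + eps)
        expr = np.vstack([
            np.r_[np.full(20, np.log1p(1.9)), np.full(20, np.log1p(0.9))],
            np.r_[np.full(20, 1.0), np.full(20, 0.5)],
        ])
        genes = np.array(["boundary", "other"], dtype=object)
        labels = np.array(["a"] * 20 + ["b"] * 20)
        tab = tf.endpoint_markers(expr, genes, labels, epsilon=0.1).set_index(["cluster", "gene_id"])
        assert tab.loc[("a", "boundary"), "log2fc"] == pytest.approx(1.0, abs=1e-9)
        assert not tab.loc[("a", "boundary"), "is_marker"]

    def test_label_permutation_invariance(self):
        expr, genes, labels = _marker_fixture()
        a = tf.endpoint_markers(expr, genes, labels)
        relabeled = np.where(labels == "a", "z", "y")
        b = tf.endpoint_markers(expr, genes, relabeled)
        for cl_old, cl_new in (("a", "z"), ("b", "y")):
            old = a[a["cluster"] == cl_old].set_index("gene_id")
            new = b[b["cluster"] == cl_new].set_index("gene_id")
            np.testing.assert_allclose(old["log2fc"], new.loc[old.index, "log2fc"])
            assert (old["is_marker"] == new.loc[old.index, "is_marker"]).all()

    def test_single_cluster_errors(self):
        expr, genes, labels = _marker_fixture()
        with pytest.raises(ValueError):
            tf.endpoint_markers(expr, genes, np.array(["a"] * len(labels)))
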