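"""Elastic principal tree: fitting geometry, grammar topology, stitching,
projection optimality (brute-force oracle) and pseudotime arithmetic."""

import numpy as np
import pytest

import treefates as tf
from treefates.tree import PrincipalTree, elastic_energy, propose_root


def _line_points(n=100, seed=0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 4, n)
    return np.column_stack([t, np.zeros(n)])


class TestFitElasticTree:
    def test_straight_segment_recovered(self):
        pts = _line_points()
        tree = tf.fit_elastic_tree(pts, n_nodes=5, seed=0)
        # all nodes within 1e-3 of the y=0 line, path topology
        assert np.all(np.abs(tree.node_positions[:, 1]) < 1e-3)
        assert tree.degrees().max() == 2
        assert len(tree.leaves()) == 2

    def test_y_skeleton_topology(self, y_points):
        tree = tf.fit_elastic_tree(y_points, n_nodes=10, seed=0)
        assert len(tree.leaves()) == 3
        assert len(tree.branch_nodes()) == 1
        assert tree.degrees().max() == 3

    def test_large_lambda_collapses_edges(self):
        pts = _line_points()
        loose = tf.fit_elastic_tree(pts, n_nodes=5, lambda_=0.001, seed=0)
        tight = tf.fit_elastic_tree(pts, n_nodes=5, lambda_=100.0, seed=0)
        assert tight.edge_lengths().sum() < 0.05 * loose.edge_lengths().sum()

    def test_curve_mode_stays_path(self, y_points):
        curve = tf.fit_elastic_tree(y_points, n_nodes=8, seed=0, curve=True)
        assert curve.degrees().max() == 2
        assert len(curve.leaves()) == 2

    def test_errors(self):
        pts = _line_points(10)
        with pytest.raises(ValueError):
            tf.fit_elastic_tree(pts, n_nodes=11)
        with pytest.raises(ValueError):
            tf.fit_elastic_tree(np.array([[np.nan, 0.0]] * 5), n_nodes=2)

    def test_energy_decreases_with_more_nodes(self):
        pts = _line_points(200, seed=3)
        e = []
        for n in (2, 4, 8):
            t = tf.fit_elastic_tree(pts, n_nodes=n, seed=0)
            e.append(elastic_energy(pts, t.node_positions, t.edges, t.lambda_, t.mu))
        assert e[2] < e[0]


class TestAttachComponent:
    def _base(self):
        return PrincipalTree(np.array([[1.0, 1.0], [3.0, 1.0]]), [(0, 1)])

    def test_centroid_mode(self):
        out = tf.attach_component(self._base(), np.array([[0.0, 0.0], [2.0, 0.0]]), mode="centroid")
        np.testing.assert_allclose(out.node_positions[2], [1.0, 0.0])
        assert (0, 2) in out.edges  # linked to nearest node (1,1)
        assert out.n_nodes == 3 and len(out.edges) == 2

    def test_subtree_mode_counts(self, rng):
        base = tf.fit_elastic_tree(_line_points(80), n_nodes=30, seed=0)
        pts = rng.normal([10, 5], 0.2, size=(60, 2)) + np.outer(rng.uniform(0, 3, 60), [1, 0])
        out = tf.attach_component(base, pts, mode="subtree", n_nodes=4)
        assert out.n_nodes == 34 and len(out.edges) == 33

    def test_curve_mode_two_leaves(self, rng):
        base = tf.fit_elastic_tree(_line_points(80), n_nodes=10, seed=0)
        t = rng.uniform(0, 4, 100)
        pts = np.column_stack([8 + t, 3 + 0.3 * t**2])
        out = tf.attach_component(base, pts, mode="curve", n_nodes=15)
        assert out.n_nodes == 25
        sub_ids = set(range(10, 25))
        deg = out.degrees()
        link_edges = [e for e in out.edges if (e[0] in sub_ids) != (e[1] in sub_ids)]
        assert len(link_edges) == 1
        # the attached curve subgraph is a path: exactly 2 of its nodes have
        # degree 1 within the subgraph
        sub_deg = {i: 0 for i in sub_ids}
        for a, b in out.edges:
            if a in sub_ids and b in sub_ids:
                sub_deg[a] += 1
                sub_deg[b] += 1
        assert sorted(sub_deg.values()).count(1) == 2

    def test_empty_points_rejected(self):
        with pytest.raises(ValueError):
            tf.attach_component(self._base(), np.empty((0, 2)))


class TestSubdivideEdges:
    def test_midpoint_example(self):
        tree = PrincipalTree(np.array([[0.0, 0.0], [2.0, 0.0]]), [(0, 1)])
        out = tf.subdivide_edges(tree)
        assert out.n_nodes == 3 and len(out.edges) == 2
        assert any(np.allclose(p, [1.0, 0.0]) for p in out.node_positions)

    def test_count_arithmetic(self, y_points):
        tree = tf.fit_elastic_tree(y_points, n_nodes=10, seed=0)
        out = tf.subdivide_edges(tree)
        assert out.n_nodes == 10 + 9 and len(out.edges) == 18

    def test_geometry_preserved(self, y_points):
        tree = tf.fit_elastic_tree(y_points, n_nodes=10, seed=0)
        out = tf.subdivide_edges(tree)
        assert out.edge_lengths().sum() == pytest.approx(tree.edge_lengths().sum(), abs=1e-12)

    def test_double_subdivision_quadruples(self, y_points):
        tree = tf.fit_elastic_tree(y_points, n_nodes=6, seed=0)
        out = tf.subdivide_edges(tf.subdivide_edges(tree))
        assert len(out.edges) == 4 * len(tree.edges)
        assert out.edge_lengths().sum() == pytest.approx(tree.edge_lengths().sum(), abs=1e-12)


class TestProjection:
    def test_orthogonal_projection(self):
        tree = PrincipalTree(np.array([[0.0, 0.0], [2.0, 0.0]]), [(0, 1)])
        [p] = tf.project_cells(tree, np.array([[1.0, 1.0]]))
        assert p.offset == pytest.approx(0.5)
        np.testing.assert_allclose(p.coordinates(tree), [1.0, 0.0])

    def test_clamping(self):
        tree = PrincipalTree(np.array([[0.0, 0.0], [2.0, 0.0]]), [(0, 1)])
        [p] = tf.project_cells(tree, np.array([[5.0, 1.0]]))
        assert p.offset == 1.0

    def test_brute_force_oracle(self, y_points, rng):
        """Chosen projection is at least as close as a dense sampling of
        every edge (10^4 samples per edge)."""
        tree = tf.fit_elastic_tree(y_points, n_nodes=8, seed=0)
        pts = rng.uniform(-1, 1, size=(50, 2))
        projs = tf.project_cells(tree, pts)
        ts = np.linspace(0, 1, 10_000)
        for x, pr in zip(pts, projs):
            best = np.inf
            for a, b in tree.edges:
                seg = tree.node_positions[a][None] * (1 - ts[:, None]) + tree.node_positions[b][None] * ts[:, None]
                best = min(best, np.linalg.norm(seg - x, axis=1).min())
            chosen = np.linalg.norm(pr.coordinates(tree) - x)
            assert chosen <= best + 1e-6

    def test_empty_tree_errors(self):
        tree = PrincipalTree(np.zeros((1, 2)), [])
        with pytest.raises(ValueError):
            tf.project_cells(tree, np.zeros((3, 2)))


class TestPseudotime:
    def _path_tree(self):
        # root - a - b with edge lengths 1.0 and 2.0
        return PrincipalTree(np.array([[0.0, 0.0], [1.0, 0.0], [3.0, 0.0]]), [(0, 1), (1, 2)], roots=[0])

    def test_root_cell_zero(self):
        tree = self._path_tree()
        projs = tf.project_cells(tree, np.array([[0.0, 0.0]]))
        [p] = tf.compute_pseudotime(tree, projs, 0)
        assert p.pseudotime == pytest.approx(0.0)

    def test_path_length_arithmetic(self):
        tree = self._path_tree()
        projs = tf.project_cells(tree, np.array([[2.0, 0.5]]))  # midpoint of a-b
        [p] = tf.compute_pseudotime(tree, projs, 0)
        assert p.pseudotime == pytest.approx(2.0)

    def test_monotone_along_path(self):
        tree = self._path_tree()
        xs = np.column_stack([np.linspace(0, 3, 30), np.zeros(30)])
        projs = tf.compute_pseudotime(tree, tf.project_cells(tree, xs), 0)
        pt = [p.pseudotime for p in projs]
        assert np.all(np.diff(pt) >= -1e-12)

    def test_two_roots_partition(self):
        # path of 3 segments: leftmost and rightmost are roots
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [2.0, 0.0], [3.0, 0.0]])
        tree = PrincipalTree(pos, [(0, 1), (1, 2), (1, 3), (3, 4)], roots=[0, 4])
        segs = tree.segments()
        # assign each segment to the root on its side
        assignment = {}
        for i, path in enumerate(segs):
            assignment[i] = 0 if 0 in path or 2 in path else 4
        xs = np.array([[0.2, 0.0], [2.9, 0.0]])
        projs = tf.compute_pseudotime(tree, tf.project_cells(tree, xs), assignment)
        assert projs[0].assigned_root == 0 and projs[0].pseudotime == pytest.approx(0.2)
        assert projs[1].assigned_root == 4 and projs[1].pseudotime == pytest.approx(0.1)

    def test_unassigned_segment_errors(self):
        tree = self._path_tree()
        projs = tf.project_cells(tree, np.array([[2.0, 0.0]]))
        with pytest.raises(ValueError, match="root"):
            tf.compute_pseudotime(tree, projs, {})


def test_json_roundtrip(tmp_path, y_points):
    tree = tf.fit_elastic_tree(y_points, n_nodes=6, seed=0)
    tree.roots = [0]
    tree.to_json(tmp_path / "tree.json")
    back = PrincipalTree.from_json(tmp_path / "tree.json")
    np.testing.assert_allclose(back.node_positions, tree.node_positions)
    assert back.edges == tree.edges and back.roots == tree.roots


def test_propose_root_votes_earliest(y_points):
    tree = tf.fit_elastic_tree(y_points, n_nodes=6, seed=0)
    projs = tf.project_cells(tree, y_points)
    early = y_points[:, 0] > 0.8  # stem tip
    root = propose_root(tree, projs, early)
    tip = tree.node_positions[root]
    assert tip[0] > 0.5
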