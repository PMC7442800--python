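"""Elastic principal trees: fitting, stitching, cell projection, pseudotime.

A principal tree is an acyclic graph of nodes embedded in the same space as
the cells (typically the first diffusion components). It is fitted by
minimizing an elastic energy

    E = MSE + lambda * sum_edges ||edge||^2 + mu * sum_stars ||v - mean(neighbors)||^2

where MSE is the mean squared distance from each point to its nearest node,
the lambda term penalizes stretching and the mu term penalizes bending at
nodes of degree >= 2. The tree is grown from a two-node seed by grammar
moves (bisect an edge / add a node to a node), each step accepting the
energy-minimizing candidate; for a fixed topology, nearest-node assignment
alternates with a closed-form quadratic update of all node positions, so
the energy never increases across iterations.

Cells are projected onto the closest point of the union of edge segments;
pseudotime is the along-tree graph distance from an assigned root to the
projected point. Trees may declare one or two roots; each branch segment is
mapped to exactly one root and its cells inherit that root.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PrincipalTree",
    "CellProjection",
    "fit_elastic_tree",
    "attach_component",
    "subdivide_edges",
    "project_cells",
    "compute_pseudotime",
    "refine_tree",
    "fit_tree_semisupervised",
    "propose_root",
    "elastic_energy",
]

DEFAULT_LAMBDA = 0.01
DEFAULT_MU = 0.1


@dataclass
class PrincipalTree:
    """Embedded principal tree: node coordinates, edges, elastic params, roots."""

    node_positions: np.ndarray  # (n_nodes, dim)
    edges: list[tuple[int, int]]
    lambda_: float = DEFAULT_LAMBDA
    mu: float = DEFAULT_MU
    roots: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.node_positions = np.asarray(self.node_positions, dtype=float)
        self.edges = [tuple(sorted(map(int, e))) for e in self.edges]
        self.edges.sort()  # canonical ordering: lexicographic (min, max)
        n = self.n_nodes
        g = self.graph()
        if len(self.edges) != n - 1 or not nx.is_connected(g):
            raise ValueError("edges must form a connected acyclic tree")
        for r in self.roots:
            if not 0 <= r < n:
                raise ValueError(f"root {r} is not a valid node id")
        if self.lambda_ < 0 or self.mu < 0:
            raise ValueError("elastic penalties must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def dim(self) -> int:
        return self.node_positions.shape[1]

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for a, b in self.edges:
            g.add_edge(a, b, length=float(np.linalg.norm(self.node_positions[a] - self.node_positions[b])))
        return g

    def edge_lengths(self) -> np.ndarray:
        return np.array(
            [np.linalg.norm(self.node_positions[a] - self.node_positions[b]) for a, b in self.edges]
        )

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def leaves(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.degrees() == 1)]

    def branch_nodes(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.degrees() >= 3)]

    def segments(self) -> list[list[int]]:
        """Branch decomposition: maximal node paths between nodes of degree != 2.

        Each segment is a node path whose endpoints are branching or terminal
        nodes and whose interior nodes all have degree 2. Segments are sorted
        by their canonical (min endpoint, max endpoint) pair.
        """
        g = self.graph()
        deg = self.degrees()
        anchors = [i for i in range(self.n_nodes) if deg[i] != 2]
        if not anchors:  # a cycle cannot occur; a 1-node tree has no edges
            return [[0]] if self.n_nodes == 1 else []
        segs, seen_edges = [], set()
        for a in anchors:
            for nb in g.neighbors(a):
                if (a, nb) in seen_edges:
                    continue
                path = [a, nb]
                seen_edges.add((a, nb))
                seen_edges.add((nb, a))
                while deg[path[-1]] == 2:
                    nxt = [x for x in g.neighbors(path[-1]) if x != path[-2]][0]
                    seen_edges.add((path[-1], nxt))
                    seen_edges.add((nxt, path[-1]))
                    path.append(nxt)
                if path[0] < path[-1] or (path[0] == path[-1]):
                    segs.append(path)
        segs.sort(key=lambda p: (min(p[0], p[-1]), max(p[0], p[-1])))
        return segs

    def to_json(self, path: str | Path) -> None:
        obj = {
            "nodes": [{"id": i, "coordinates": list(map(float, p))} for i, p in enumerate(self.node_positions)],
            "edges": [list(e) for e in self.edges],
            "roots": list(map(int, self.roots)),
            "lambda": self.lambda_,
            "mu": self.mu,
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PrincipalTree":
        obj = json.loads(Path(path).read_text())
        pos = np.array([n["coordinates"] for n in sorted(obj["nodes"], key=lambda n: n["id"])])
        return cls(pos, [tuple(e) for e in obj["edges"]], obj["lambda"], obj["mu"], obj["roots"])


@dataclass
class CellProjection:
    """A cell's position on the tree and its pseudotime."""

    cell_id: str
    edge: tuple[int, int]
    offset: float  # in [0, 1] from edge[0] to edge[1]
    segment: int = -1
    pseudotime: float = np.nan
    assigned_root: int = -1

    def coordinates(self, tree: PrincipalTree) -> np.ndarray:
        a, b = self.edge
        return (1 - self.offset) * tree.node_positions[a] + self.offset * tree.node_positions[b]


def projections_to_frame(projections: list[CellProjection]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in projections],
            "edge": [f"{p.edge[0]}-{p.edge[1]}" for p in projections],
            "offset": [p.offset for p in projections],
            "pseudotime": [p.pseudotime for p in projections],
            "segment": [p.segment for p in projections],
            "root": [p.assigned_root for p in projections],
        }
    ).set_index("cell_id")


# ---------------------------------------------------------------------------
# elastic energy and fitting


def _assign(points: np.ndarray, positions: np.ndarray) -> np.ndarray:
    d2 = ((points[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
    return d2.argmin(axis=1)


def elastic_energy(
    points: np.ndarray,
    positions: np.ndarray,
    edges: list[tuple[int, int]],
    lambda_: float,
    mu: float,
    assignment: np.ndarray | None = None,
) -> float:
    """Total elastic energy of a tree configuration for the given points."""
    if assignment is None:
        assignment = _assign(points, positions)
    mse = ((points - positions[assignment]) ** 2).sum(-1).mean()
    stretch = sum(((positions[a] - positions[b]) ** 2).sum() for a, b in edges)
    deg: dict[int, list[int]] = {}
    for a, b in edges:
        deg.setdefault(a, []).append(b)
        deg.setdefault(b, []).append(a)
    bend = 0.0
    for j, nbrs in deg.items():
        if len(nbrs) >= 2:
            bend += ((positions[j] - positions[nbrs].mean(axis=0)) ** 2).sum()
    return float(mse + lambda_ * stretch + mu * bend)


def _solve_positions(
    points: np.ndarray,
    n_nodes: int,
    edges: list[tuple[int, int]],
    assignment: np.ndarray,
    lambda_: float,
    mu: float,
) -> np.ndarray:
    """Closed-form quadratic update of all node positions given assignments."""
    n_pts = points.shape[0]
    counts = np.bincount(assignment, minlength=n_nodes) / n_pts
    q = np.diag(counts.astype(float))
    b = np.zeros((n_nodes, points.shape[1]))
    np.add.at(b, assignment, points / n_pts)
    for a_, b_ in edges:
        q[a_, a_] += lambda_
        q[b_, b_] += lambda_
        q[a_, b_] -= lambda_
        q[b_, a_] -= lambda_
    nbrs: dict[int, list[int]] = {i: [] for i in range(n_nodes)}
    for a_, b_ in edges:
        nbrs[a_].append(b_)
        nbrs[b_].append(a_)
    for j, nb in nbrs.items():
        k = len(nb)
        if k < 2:
            continue
        # s = e_j - mean(e_neighbors); add mu * s s^T
        idx = [j] + nb
        coef = np.array([1.0] + [-1.0 / k] * k)
        for p, i in enumerate(idx):
            for r, l in enumerate(idx):
                q[i, l] += mu * coef[p] * coef[r]
    return np.linalg.solve(q + 1e-12 * np.eye(n_nodes), b)


def _optimize(
    points: np.ndarray,
    positions: np.ndarray,
    edges: list[tuple[int, int]],
    lambda_: float,
    mu: float,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Alternate nearest-node assignment and quadratic position updates.

    Energy is asserted non-increasing across iterations (up to numerical
    slack): both half-steps minimize the energy in their own variables.
    """
    energy = elastic_energy(points, positions, edges, lambda_, mu)
    for _ in range(max_iter):
        assignment = _assign(points, positions)
        positions = _solve_positions(points, positions.shape[0], edges, assignment, lambda_, mu)
        new_energy = elastic_energy(points, positions, edges, lambda_, mu)
        assert new_energy <= energy + 1e-9, "elastic energy increased during optimization"
        if energy - new_energy < tol:
            energy = new_energy
            break
        energy = new_energy
    return positions, energy


def _candidate_moves(
    positions: np.ndarray, edges: list[tuple[int, int]], assignment: np.ndarray, points: np.ndarray
):
    """Grammar moves: bisect each edge; add a node to each existing node."""
    n = positions.shape[0]
    for a, b in edges:
        mid = (positions[a] + positions[b]) / 2
        new_edges = [e for e in edges if e != (a, b)] + [(a, n), (b, n)]
        yield np.vstack([positions, mid]), new_edges
    for j in range(n):
        pts_j = points[assignment == j]
        if pts_j.shape[0] >= 2:
            new_pos = pts_j.mean(axis=0)
            if np.allclose(new_pos, positions[j]):
                new_pos = positions[j] + 1e-6
        else:
            new_pos = positions[j] + 1e-6
        yield np.vstack([positions, new_pos]), edges + [(j, n)]


def _rewire_pass(
    points: np.ndarray,
    positions: np.ndarray,
    edges: list[tuple[int, int]],
    lambda_: float,
    mu: float,
    max_passes: int = 5,
    n_candidates: int = 5,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Escape topological local optima by spanning-tree rewiring.

    Greedy growth can leave a branch attached at the wrong end (a long
    chord plus a backward spur). Each rewire adds a candidate edge between
    two nearby nodes, removes the edge of the induced cycle that frees the
    most energy, and keeps the change only when the total elastic energy
    decreases after re-optimizing positions. Energy is monotone
    non-increasing across accepted rewires.
    """
    positions = positions.copy()
    edges = list(edges)
    n = positions.shape[0]
    energy = elastic_energy(points, positions, edges, lambda_, mu)
    for _ in range(max_passes):
        improved = False
        g = nx.Graph(edges)
        d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        for a in range(n):
            order = np.argsort(d2[a])[: n_candidates + len(list(g.neighbors(a)))]
            for b in order:
                b = int(b)
                if b <= a or g.has_edge(a, b):
                    continue
                cycle = nx.shortest_path(g, a, b)
                cycle_edges = list(zip(cycle[:-1], cycle[1:]))
                lengths = [((positions[u] - positions[v]) ** 2).sum() for u, v in cycle_edges]
                if d2[a, b] >= max(lengths):
                    continue  # the new edge would be no shorter than what it replaces
                # try removing each of the longest few cycle edges
                best_cand = None
                for k in np.argsort(lengths)[::-1][:3]:
                    u, v = cycle_edges[int(k)]
                    cand = [e for e in edges if e != tuple(sorted((u, v)))] + [tuple(sorted((a, b)))]
                    cand_pos, cand_energy = _optimize(points, positions, cand, lambda_, mu, max_iter=10)
                    if cand_energy < energy - 1e-12 and (best_cand is None or cand_energy < best_cand[0]):
                        best_cand = (cand_energy, cand_pos, cand)
                if best_cand is not None:
                    energy, positions, edges = best_cand
                    g = nx.Graph(edges)
                    d2 = ((positions[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
                    np.fill_diagonal(d2, np.inf)
                    improved = True
        if not improved:
            break
    positions, energy = _optimize(points, positions, edges, lambda_, mu)
    return positions, edges


def refine_tree(tree: PrincipalTree, points: np.ndarray, rewire: bool = True) -> PrincipalTree:
    """Continue elastic optimization of an existing tree on the given points,
    optionally with topology rewiring; used after edge subdivision to let the
    finer tree settle into the data."""
    points = np.asarray(points, dtype=float)
    positions, _ = _optimize(points, tree.node_positions, tree.edges, tree.lambda_, tree.mu)
    edges = tree.edges
    if rewire:
        positions, edges = _rewire_pass(points, positions, edges, tree.lambda_, tree.mu)
    return PrincipalTree(positions, edges, tree.lambda_, tree.mu, tree.roots)


def fit_tree_semisupervised(
    points: np.ndarray,
    cluster_labels: np.ndarray,
    n_nodes_per_cluster: int = 10,
    lambda_: float = DEFAULT_LAMBDA,
    mu: float = DEFAULT_MU,
    seed: int = 0,
) -> PrincipalTree:
    """Stitch a principal tree from per-cluster principal curves.

    Mirrors the semi-supervised protocol used for real branching data: an
    elastic principal curve is fitted to each cluster's cells separately,
    then curves are merged greedily -- at each step the unattached curve
    whose nearest node is closest to the current tree is linked to the tree
    through that closest node pair. Per-cluster curves cannot thread a
    branch backwards, which makes the stitched topology far more robust
    than a single unsupervised fit when branch corridors meet in narrow
    regions of the embedding.
    """
    points = np.asarray(points, dtype=float)
    cluster_labels = np.asarray(cluster_labels)
    names = list(pd.unique(cluster_labels))
    curves = {}
    for nm in names:
        pts = points[cluster_labels == nm]
        n_nodes = min(n_nodes_per_cluster, max(2, pts.shape[0] // 3))
        curves[nm] = fit_elastic_tree(pts, n_nodes, lambda_, mu, seed=seed, curve=True)

    start = max(names, key=lambda nm: (cluster_labels == nm).sum())
    tree = curves.pop(start)
    while curves:
        best = None
        for nm, cv in curves.items():
            d = ((cv.node_positions[:, None, :] - tree.node_positions[None, :, :]) ** 2).sum(-1)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if best is None or d[i, j] < best[0]:
                best = (d[i, j], nm, int(i), int(j))
        _, nm, i, j = best
        cv = curves.pop(nm)
        n0 = tree.n_nodes
        pos = np.vstack([tree.node_positions, cv.node_positions])
        edges = tree.edges + [(a + n0, b + n0) for a, b in cv.edges] + [(j, i + n0)]
        tree = PrincipalTree(pos, edges, lambda_, mu, tree.roots)
    return tree


def fit_elastic_tree(
    points: np.ndarray,
    n_nodes: int,
    lambda_: float = DEFAULT_LAMBDA,
    mu: float = DEFAULT_MU,
    seed: int = 0,
    curve: bool = False,
) -> PrincipalTree:
    """Fit an elastic principal tree (or curve) to a point cloud.

    The tree is grown from a 2-node seed placed at the two most distant
    points of a random subsample, adding one node per step by the
    energy-minimizing grammar move. With ``curve=True`` moves that would
    create a node of degree >= 3 are rejected, so the result is a path
    (principal curve).
    """
    points = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(points)):
        raise ValueError("non-finite coordinates in input points")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if points.shape[0] < n_nodes:
        raise ValueError("need at least as many points as nodes")

    rng = np.random.default_rng(seed)
    sub = points[rng.choice(points.shape[0], size=min(100, points.shape[0]), replace=False)]
    d2 = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    positions = np.vstack([sub[i], sub[j]])
    edges: list[tuple[int, int]] = [(0, 1)]
    positions, energy = _optimize(points, positions, edges, lambda_, mu)

    while positions.shape[0] < n_nodes:
        assignment = _assign(points, positions)
        best = None
        for cand_pos, cand_edges in _candidate_moves(positions, edges, assignment, points):
            if curve:
                deg = np.zeros(cand_pos.shape[0], dtype=int)
                for a, b in cand_edges:
                    deg[a] += 1
                    deg[b] += 1
                if deg.max() > 2:
                    continue
            cand_pos, cand_energy = _optimize(points, cand_pos, cand_edges, lambda_, mu, max_iter=10)
            if best is None or cand_energy < best[0]:
                best = (cand_energy, cand_pos, cand_edges)
        _, positions, edges = best
        positions, energy = _optimize(points, positions, edges, lambda_, mu)

    edges = [tuple(sorted(e)) for e in edges]
    if not curve:
        positions, edges = _rewire_pass(points, positions, edges, lambda_, mu)
    return PrincipalTree(positions, edges, lambda_, mu)


# ---------------------------------------------------------------------------
# stitching operations


def attach_component(
    tree: PrincipalTree,
    points: np.ndarray,
    mode: str = "centroid",
    n_nodes: int = 4,
    seed: int = 0,
) -> PrincipalTree:
    """Attach a new component to an existing tree.

    ``centroid``: add a single node at the mean of ``points``, linked to the
    nearest existing node. ``subtree``/``curve``: fit a separate principal
    tree (or path-constrained curve) of ``n_nodes`` on ``points`` and link
    its node nearest to the main tree to the main tree's nearest node. The
    result is always one connected acyclic graph.
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        raise ValueError("no points to attach")
    n0 = tree.n_nodes
    if mode == "centroid":
        new_pos = points.mean(axis=0, keepdims=True)
        add_edges: list[tuple[int, int]] = []
        link_from = n0  # the centroid node itself
    elif mode in ("subtree", "curve"):
        sub = fit_elastic_tree(points, n_nodes, tree.lambda_, tree.mu, seed=seed, curve=(mode == "curve"))
        new_pos = sub.node_positions
        add_edges = [(a + n0, b + n0) for a, b in sub.edges]
        d = ((new_pos[:, None, :] - tree.node_positions[None, :, :]) ** 2).sum(-1)
        link_from = n0 + int(np.unravel_index(np.argmin(d), d.shape)[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    d_main = ((tree.node_positions - new_pos[link_from - n0]) ** 2).sum(-1)
    link_to = int(np.argmin(d_main))
    all_pos = np.vstack([tree.node_positions, new_pos])
    all_edges = tree.edges + add_edges + [(link_to, link_from)]
    out = PrincipalTree(all_pos, all_edges, tree.lambda_, tree.mu, tree.roots)
    assert nx.is_tree(out.graph()), "attachment created a cycle"
    return out


def subdivide_edges(tree: PrincipalTree) -> PrincipalTree:
    """Split every edge in two at its midpoint; geometry is unchanged."""
    pos = [tree.node_positions]
    new_edges = []
    n = tree.n_nodes
    for k, (a, b) in enumerate(tree.edges):
        mid = (tree.node_positions[a] + tree.node_positions[b]) / 2
        pos.append(mid[None, :])
        new_edges += [(a, n + k), (b, n + k)]
    return PrincipalTree(np.vstack(pos), new_edges, tree.lambda_, tree.mu, tree.roots)


# ---------------------------------------------------------------------------
# projection and pseudotime


def project_cells(
    tree: PrincipalTree, points: np.ndarray, cell_ids=None
) -> list[CellProjection]:
    """Project each cell onto the closest point of the union of edge segments.

    Continuous orthogonal projection onto each edge, clamped to the segment;
    ties broken by the lowest edge index in canonical edge ordering.
    """
    points = np.asarray(points, dtype=float)
    if points.shape[1] != tree.dim:
        raise ValueError("points and tree have different dimensionality")
    if not tree.edges:
        raise ValueError("tree has no edges")
    if cell_ids is None:
        cell_ids = [f"cell_{i}" for i in range(points.shape[0])]

    starts = tree.node_positions[[a for a, _ in tree.edges]]
    ends = tree.node_positions[[b for _, b in tree.edges]]
    vec = ends - starts  # (E, dim)
    len2 = np.maximum((vec**2).sum(-1), 1e-300)

    diff = points[:, None, :] - starts[None, :, :]  # (N, E, dim)
    t = np.clip((diff * vec[None]).sum(-1) / len2[None], 0.0, 1.0)  # (N, E)
    proj = starts[None] + t[..., None] * vec[None]
    d2 = ((points[:, None, :] - proj) ** 2).sum(-1)
    # canonical tie-break: argmin returns the first (lowest edge index)
    best = np.argmin(np.round(d2, 12), axis=1)

    out = []
    for idx, cid in enumerate(cell_ids):
        e = best[idx]
        out.append(CellProjection(cell_id=str(cid), edge=tree.edges[e], offset=float(t[idx, e])))
    return out


def propose_root(tree: PrincipalTree, projections: list[CellProjection], early_mask: np.ndarray) -> int:
    """Propose as root the node nearest to the most earliest-timepoint cells."""
    votes = np.zeros(tree.n_nodes, dtype=int)
    for p, early in zip(projections, early_mask):
        if early:
            a, b = p.edge
            votes[a if p.offset < 0.5 else b] += 1
    return int(np.argmax(votes))


def compute_pseudotime(
    tree: PrincipalTree,
    projections: list[CellProjection],
    root_assignment: dict[int, int] | int,
) -> list[CellProjection]:
    """Pseudotime = along-tree graph distance from the assigned root.

    ``root_assignment`` maps segment index -> root node id (or a single
    root id for the whole tree). Every segment must reach its root.
    """
    segs = tree.segments()
    if isinstance(root_assignment, (int, np.integer)):
        root_assignment = {i: int(root_assignment) for i in range(len(segs))}
    roots = sorted(set(root_assignment.values()))
    g = tree.graph()
    dist = {r: nx.single_source_dijkstra_path_length(g, r, weight="length") for r in roots}

    # map each edge to its segment (canonical segment order)
    edge_seg: dict[tuple[int, int], int] = {}
    for si, path in enumerate(segs):
        for a, b in zip(path[:-1], path[1:]):
            edge_seg[tuple(sorted((a, b)))] = si

    out = []
    for p in projections:
        a, b = p.edge
        si = edge_seg[tuple(sorted((a, b)))]
        if si not in root_assignment:
            raise ValueError(f"segment {si} has no assigned root")
        r = root_assignment[si]
        if a not in dist[r]:
            raise ValueError(f"segment {si} cannot reach root {r}")
        length = float(np.linalg.norm(tree.node_positions[a] - tree.node_positions[b]))
        pt = min(dist[r][a] + p.offset * length, dist[r][b] + (1 - p.offset) * length)
        out.append(
            CellProjection(
                cell_id=p.cell_id,
                edge=p.edge,
                offset=p.offset,
                segment=si,
                pseudotime=float(pt),
                assigned_root=r,
            )
        )
    return out
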