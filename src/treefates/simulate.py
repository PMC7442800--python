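"""Synthetic branching scRNA-seq generator with known ground truth.

Emulates a rooted branching differentiation process as sampled by a
high-coverage plate-based (Smart-seq2 style, non-UMI) protocol: cells are
placed along a segment tree in pseudotime; gene programs switch on as
sigmoids positioned in pseudotime; competing pre-fork "early" modules are
co-activated before their bifurcation and become branch-exclusive after
it; "late" modules are branch-exclusive from the start; "identity" genes
activate near the root on every path; counts are negative-binomial with
independent dropout, per-cell depth variation and ERCC spike-in
pseudo-genes.

To mirror the gradual fate biasing seen before a bifurcation, each pre-fork
cell carries a latent fate for every competing module pair; the bias of its
expression toward the favored module ramps up as the cell approaches the
fork (``bias_amplitude`` controls the strength, 0 disables it). After the
fork the cell's branch is its fate. This makes opposing early modules
progressively anti-correlated across cells at matched pseudotime while
both are still rising on average -- the biasing signature the module
correlation tracks are designed to detect.

All randomness flows from ``SimulationConfig.seed``; identical seeds give
identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CellAnnotation, CountMatrix, write_count_matrix
from .tree import PrincipalTree

__all__ = [
    "Segment",
    "ModuleSpec",
    "SimulationConfig",
    "SyntheticGroundTruth",
    "SyntheticDataset",
    "evaluate_activation_profile",
    "simulate_dataset",
    "default_config",
    "write_dataset",
]


def evaluate_activation_profile(t, t_on: float, k: float, o: float, b: float):
    """Expected log-expression of a sigmoidal activation program.

    ``b + (o - b) / (1 + exp(-k (t - t_on)))``: baseline ``b`` long before
    the activation time ``t_on``, optimum ``o`` long after, rising at rate
    ``k``. Strictly increasing in ``t`` when ``o > b``.
    """
    t = np.asarray(t, dtype=float)
    for name, v in (("t_on", t_on), ("k", k), ("o", o), ("b", b)):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    if k <= 0:
        raise ValueError("rate k must be positive")
    if o < b:
        raise ValueError("optimum must be >= baseline")
    out = b + (o - b) / (1.0 + np.exp(-k * (t - t_on)))
    return float(out) if out.ndim == 0 else out


@dataclass
class Segment:
    """A named branch segment: ``parent`` is None for a root segment."""

    name: str
    parent: str | None
    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name}: length must be > 0")


@dataclass
class ModuleSpec:
    """A gene module committed to one segment.

    Genes share a sigmoid program (activation time ``t_on``, rate ``k``,
    optimum ``o``, baseline ``b``) expressed along the committed path
    (root -> segment -> descendants) and sitting at baseline elsewhere.
    """

    name: str
    segment: str
    n_genes: int
    t_on: float
    k: float = 1.5
    o: float = 3.0
    b: float = -2.0
    t_on_jitter: float = 1.0  # per-gene activation spread (uniform +/- jitter)

    def __post_init__(self) -> None:
        if self.k <= 0 or self.o < self.b or self.n_genes < 0 or self.t_on_jitter < 0:
            raise ValueError(f"module {self.name}: invalid parameters")


@dataclass
class SimulationConfig:
    """Full description of a synthetic branching dataset."""

    segments: list[Segment]
    modules: list[ModuleSpec] = field(default_factory=list)
    n_cells_per_segment: int = 100
    n_identity_genes: int = 0
    n_noise_genes: int = 0
    nb_dispersion: float = 2.0
    dropout_rate: float = 0.1
    depth_mean: float = 1.0
    depth_cv: float = 0.3
    ercc_fraction_mean: float = 0.05
    n_ercc: int = 20
    bias_amplitude: float = 0.25
    identity_optimum: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty topology")
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        for s in self.segments:
            if s.parent is not None and s.parent not in names:
                raise ValueError(f"segment {s.name}: unknown parent {s.parent}")
        for m in self.modules:
            if m.segment not in names:
                raise ValueError(f"module {m.name} references unknown segment {m.segment}")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        if not 0 <= self.ercc_fraction_mean < 1:
            raise ValueError("ercc_fraction_mean must be in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.depth_mean <= 0 or self.depth_cv < 0:
            raise ValueError("depth parameters must be positive")

    # --- topology helpers -------------------------------------------------
    def segment_map(self) -> dict[str, Segment]:
        return {s.name: s for s in self.segments}

    def children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {s.name: [] for s in self.segments}
        for s in self.segments:
            if s.parent is not None:
                ch[s.parent].append(s.name)
        return ch

    def segment_start(self, name: str) -> float:
        """Pseudotime at which a segment begins (cumulative ancestor length)."""
        smap = self.segment_map()
        t, s = 0.0, smap[name]
        while s.parent is not None:
            s = smap[s.parent]
            t += s.length
        return t

    def ancestors(self, name: str) -> list[str]:
        smap = self.segment_map()
        out, s = [], smap[name]
        while s.parent is not None:
            out.append(s.parent)
            s = smap[s.parent]
        return out

    def descendants(self, name: str) -> list[str]:
        ch = self.children()
        out, stack = [], list(ch[name])
        while stack:
            x = stack.pop()
            out.append(x)
            stack.extend(ch[x])
        return out

    def committed_path(self, name: str) -> set[str]:
        return {name, *self.ancestors(name), *self.descendants(name)}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        segs = [Segment(**s) for s in raw.pop("segments")]
        mods = [ModuleSpec(**m) for m in raw.pop("modules", [])]
        return cls(segments=segs, modules=mods, **raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_tree: PrincipalTree
    true_pseudotime: np.ndarray
    true_segment: np.ndarray  # segment name per cell
    module_membership: dict[str, str]  # gene -> module name
    activation_params: dict[str, tuple[float, float, float, float]]  # gene -> (t_on, k, o, b)
    identity_gene_ids: set[str]


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    cells: CellAnnotation
    truth: SyntheticGroundTruth

    def __post_init__(self) -> None:
        if self.counts.n_cells != len(self.truth.true_pseudotime):
            raise ValueError("cell dimensions disagree")


def _tree_layout(config: SimulationConfig) -> tuple[PrincipalTree, dict[str, tuple[int, int]]]:
    """Planar layout of the segment tree (one node per segment endpoint)."""
    smap = config.segment_map()
    ch = config.children()
    roots = [s.name for s in config.segments if s.parent is None]
    positions: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    seg_nodes: dict[str, tuple[int, int]] = {}

    def place(seg: str, start: np.ndarray, angle: float, start_node: int | None) -> None:
        direction = np.array([np.cos(angle), np.sin(angle)])
        end = start + smap[seg].length * direction
        if start_node is None:
            positions.append(start)
            start_node = len(positions) - 1
        positions.append(end)
        end_node = len(positions) - 1
        edges.append((start_node, end_node))
        seg_nodes[seg] = (start_node, end_node)
        kids = ch[seg]
        fan = np.linspace(-0.7, 0.7, len(kids)) if len(kids) > 1 else [0.0]
        for a, kid in zip(fan, kids):
            place(kid, end, angle + a, end_node)

    for i, r in enumerate(roots):
        place(r, np.array([0.0, 3.0 * i]), 0.0, None)
    root_nodes = [seg_nodes[r][0] for r in roots]
    return PrincipalTree(np.array(positions), edges, roots=root_nodes), seg_nodes


def _competing_pairs(config: SimulationConfig) -> list[tuple[ModuleSpec, ModuleSpec]]:
    """Early-module pairs committed to sibling segments that share t_on
    and activate before their fork."""
    smap = config.segment_map()
    pairs = []
    mods = config.modules
    for i in range(len(mods)):
        for j in range(i + 1, len(mods)):
            a, b = mods[i], mods[j]
            sa, sb = smap[a.segment], smap[b.segment]
            if sa.parent is not None and sa.parent == sb.parent and a.segment != b.segment:
                fork_t = config.segment_start(a.segment)
                if a.t_on == b.t_on and a.t_on < fork_t:
                    pairs.append((a, b))
    return pairs


def expected_log_expression(config: SimulationConfig) -> tuple[np.ndarray, list[str], dict]:
    """Deterministic part of the generator: per-gene, per-cell expected
    log-expression plus cell placements; shared by the sampler and by
    law-of-large-numbers tests.

    Returns ``(mu_log, gene_ids, info)`` where ``info`` carries cell
    pseudotimes/segments, activation params, module membership and the
    latent fate draws used for pre-fork biasing.
    """
    rng = np.random.default_rng(config.seed)
    smap = config.segment_map()

    # --- cells: uniform placement along each segment ----------------------
    seg_names, pt = [], []
    for s in config.segments:
        u = np.sort(rng.uniform(0, s.length, size=config.n_cells_per_segment))
        pt.extend(config.segment_start(s.name) + u)
        seg_names.extend([s.name] * config.n_cells_per_segment)
    pt = np.array(pt)
    seg_names = np.array(seg_names, dtype=object)
    n_cells = len(pt)

    # --- gene catalogue ---------------------------------------------------
    gene_ids: list[str] = []
    membership: dict[str, str] = {}
    activation: dict[str, tuple[float, float, float, float]] = {}
    identity_ids: set[str] = set()

    rows: list[np.ndarray] = []
    pairs = _competing_pairs(config)
    # Competing early modules are modeled as one continuous program per
    # cell: pre-fork cells carry a latent fate phi = +/-1 whose biasing of
    # the two modules ramps up linearly from activation to the fork; on the
    # cell's own branch the favored multiplier (1 + bias) persists, on the
    # opposing branch expression decays exponentially from its fork-level
    # value toward baseline. Expression is continuous across the fork.
    pair_info: dict[str, dict] = {}
    for a, b in pairs:
        fork_t = config.segment_start(a.segment)
        latent = np.where(rng.random(n_cells) < 0.5, 1.0, -1.0)
        on_a = np.isin(seg_names, [a.segment, *config.descendants(a.segment)])
        on_b = np.isin(seg_names, [b.segment, *config.descendants(b.segment)])
        latent[on_a] = 1.0
        latent[on_b] = -1.0
        ramp = np.clip((pt - a.t_on) / max(fork_t - a.t_on, 1e-9), 0.0, 1.0)
        pair_info[a.name] = dict(phi=latent, ramp=ramp, own=on_a, opp=on_b, fork_t=fork_t)
        pair_info[b.name] = dict(phi=-latent, ramp=ramp, own=on_b, opp=on_a, fork_t=fork_t)

    for m in config.modules:
        committed = config.committed_path(m.segment)
        on_path = np.isin(seg_names, sorted(committed))
        # genes of a module switch on gradually, not all at once
        t_on_g = m.t_on + rng.uniform(-m.t_on_jitter, m.t_on_jitter, size=m.n_genes)
        for g in range(m.n_genes):
            prof = evaluate_activation_profile(pt, t_on_g[g], m.k, m.o, m.b)
            if m.name in pair_info:
                info = pair_info[m.name]
                amp = config.bias_amplitude
                pre = pt < info["fork_t"]
                fork_level = evaluate_activation_profile(info["fork_t"], t_on_g[g], m.k, m.o, m.b)
                decay = (fork_level - m.b) * (1 - amp) * np.exp(
                    -m.k * np.maximum(pt - info["fork_t"], 0.0)
                )
                mu = np.where(
                    info["own"],
                    m.b + (prof - m.b) * (1 + amp),
                    np.where(
                        pre & on_path,
                        m.b + (prof - m.b) * (1 + amp * info["phi"] * info["ramp"]),
                        np.where(info["opp"], m.b + decay, m.b),
                    ),
                )
            else:
                mu = np.where(on_path, prof, m.b)
            gid = f"{m.name}_g{g:03d}"
            gene_ids.append(gid)
            membership[gid] = m.name
            activation[gid] = (float(t_on_g[g]), m.k, m.o, m.b)
            rows.append(mu)

    for g in range(config.n_identity_genes):
        gid = f"ID_g{g:03d}"
        t_on = rng.uniform(0.5, 2.0)
        o, b, k = config.identity_optimum, -2.0, 1.5
        gene_ids.append(gid)
        identity_ids.add(gid)
        activation[gid] = (t_on, k, o, b)
        rows.append(evaluate_activation_profile(pt, t_on, k, o, b))

    for g in range(config.n_noise_genes):
        gid = f"NOISE_g{g:03d}"
        gene_ids.append(gid)
        rows.append(np.full(n_cells, rng.uniform(0.5, 1.5)))

    mu_log = np.array(rows) if rows else np.zeros((0, n_cells))
    info = {
        "pseudotime": pt,
        "segment": seg_names,
        "membership": membership,
        "activation": activation,
        "identity_ids": identity_ids,
        "rng": rng,
    }
    return mu_log, gene_ids, info


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw a full synthetic dataset from the generative model.

    Counts are negative-binomial around ``depth_factor * exp(mu_log)``
    (Gamma-Poisson with size ``nb_dispersion``; Poisson in the infinite-
    dispersion limit), then zeroed by Bernoulli dropout whose probability
    ``dropout_rate * exp(-mean)`` decays with expected expression. ERCC
    pseudo-genes are depth-independent Poisson scaled so each cell's
    expected spike-in fraction is log-normally jittered around
    ``ercc_fraction_mean``.
    """
    mu_log, gene_ids, info = expected_log_expression(config)
    rng: np.random.Generator = info["rng"]
    pt, seg_names = info["pseudotime"], info["segment"]
    n_genes, n_cells = mu_log.shape

    # per-cell depth factors: log-normal with mean depth_mean, CV depth_cv
    if config.depth_cv > 0:
        s2 = np.log1p(config.depth_cv**2)
        depth = rng.lognormal(np.log(config.depth_mean) - s2 / 2, np.sqrt(s2), size=n_cells)
    else:
        depth = np.full(n_cells, config.depth_mean)

    mu = depth[None, :] * np.exp(mu_log)
    if np.isinf(config.nb_dispersion):
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(config.nb_dispersion, mu / config.nb_dispersion)
        counts = rng.poisson(lam)
    if config.dropout_rate > 0:
        # dropout hits lowly expressed genes; well-detected transcripts are
        # essentially never lost in deep full-length libraries
        p_drop = config.dropout_rate * np.exp(-mu)
        counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    # ERCC spike-ins: fixed relative abundances, per-cell totals jittered
    # log-normally around the target fraction of the mean endogenous depth
    if config.n_ercc > 0 and config.ercc_fraction_mean > 0:
        mean_endo = float(np.exp(mu_log).sum(axis=0).mean() * config.depth_mean)
        frac = np.exp(rng.normal(np.log(config.ercc_fraction_mean), 0.3, size=n_cells))
        spike_totals = frac / (1 - np.minimum(frac, 0.9)) * mean_endo
        rel = np.geomspace(1.0, 0.05, config.n_ercc)
        rel /= rel.sum()
        spike_mu = rel[:, None] * spike_totals[None, :]
        spike_counts = rng.poisson(spike_mu)
        counts = np.vstack([counts, spike_counts])
        gene_ids = gene_ids + [f"ERCC-{i:05d}" for i in range(config.n_ercc)]

    cell_ids = np.array([f"cell_{i:04d}" for i in range(n_cells)], dtype=object)
    max_pt = pt.max()
    stages = ["E9.5", "E10.5", "E11.5", "E12.5"]
    timepoint = [stages[min(int(t / (max_pt + 1e-9) * 4), 3)] for t in pt]
    cells = CellAnnotation.from_arrays(
        cell_ids, timepoint=timepoint, tracing_line="Wnt1Cre", cluster_label=list(seg_names)
    )
    true_tree, _ = _tree_layout(config)
    truth = SyntheticGroundTruth(
        true_tree=true_tree,
        true_pseudotime=pt,
        true_segment=seg_names,
        module_membership=info["membership"],
        activation_params=info["activation"],
        identity_gene_ids=info["identity_ids"],
    )
    return SyntheticDataset(
        counts=CountMatrix(counts, np.array(gene_ids, dtype=object), cell_ids),
        cells=cells,
        truth=truth,
    )


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The standard study conditions: a two-fork tree with competing early
    modules at the first fork, branch-exclusive late modules, ubiquitous
    root-activated identity genes and flat noise genes.

    Trunk of 6 pseudotime units (the progenitor pool), a first fork into
    two branches of 6 units, and a second fork splitting branch A. Early
    modules activate at t=4 (before the fork at t=6); late modules at t=8.
    """
    segments = [
        Segment("trunk", None, 6.0),
        Segment("branchA", "trunk", 6.0),
        Segment("branchB", "trunk", 6.0),
        Segment("branchA1", "branchA", 4.0),
        Segment("branchA2", "branchA", 4.0),
    ]
    modules = [
        ModuleSpec("earlyA", "branchA", 20, t_on=4.0),
        ModuleSpec("earlyB", "branchB", 20, t_on=4.0),
        ModuleSpec("lateA", "branchA", 20, t_on=8.0),
        ModuleSpec("lateB", "branchB", 20, t_on=8.0),
        ModuleSpec("earlyA1", "branchA1", 15, t_on=10.0),
        ModuleSpec("earlyA2", "branchA2", 15, t_on=10.0),
        ModuleSpec("lateA1", "branchA1", 15, t_on=13.0),
        ModuleSpec("lateA2", "branchA2", 15, t_on=13.0),
    ]
    cfg = dict(
        segments=segments,
        modules=modules,
        n_cells_per_segment=100,
        n_identity_genes=40,
        n_noise_genes=200,
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write counts (MTX + id tables), cell annotations, and ground truth
    (delimited tables + JSON tree)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(dataset.counts, out / "counts")
    dataset.cells.table.to_csv(out / "cells.tsv", sep="\t")
    truth = dataset.truth
    pd.DataFrame(
        {
            "cell_id": dataset.counts.cell_ids,
            "true_pseudotime": truth.true_pseudotime,
            "true_segment": truth.true_segment,
        }
    ).to_csv(out / "truth_cells.tsv", sep="\t", index=False)
    rows = []
    for gid, params in truth.activation_params.items():
        rows.append(
            {
                "gene_id": gid,
                "module": truth.module_membership.get(gid, "identity" if gid in truth.identity_gene_ids else "none"),
                "t_on": params[0],
                "k": params[1],
                "o": params[2],
                "b": params[3],
            }
        )
    pd.DataFrame(rows).to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    truth.true_tree.to_json(out / "true_tree.json")
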