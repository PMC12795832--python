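"""Synthetic two-sample branching-trajectory single-cell data.

The generator emulates the statistical structure the valley-ridge analysis
assumes, with ground truth attached:

* a cluster tree (root -> internal -> leaf) shared by two samples, plus
  optional extra root clusters present only in the second ("KO-analog")
  sample;
* gene-wise connectome degrees drawn from a heavy-tailed law with designated
  hubs; root-cluster cells express a broad program whose per-gene mean is
  proportional to degree**alpha, so their transcriptome-degree correlation
  (CCAT) is high by construction, while leaf clusters express random marker
  programs uncorrelated with degree;
* a two-regime transcription model per gene with splicing ratio gamma_j:
  cells of root and leaf clusters sit at steady state (E[u] = gamma * E[s]),
  cells of internal, transitional clusters carry surplus unspliced transcript
  (E[u] = boost * gamma * E[s]), so velocity lengths are low at attractors
  and high in transit, matching the flags in the returned ground truth;
* negative-binomial counts around those means, and a 2-D embedding placing
  clusters at tree-layout positions with Gaussian jitter.

Everything is drawn from one ``numpy`` generator seeded by ``SimConfig.seed``;
identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cells import CLUSTER, SAMPLE
from .exceptions import ValidationError
from .io import CountMatrixPair

__all__ = ["SimConfig", "GroundTruth", "SpatialSection", "simulate_tree", "simulate_spatial"]


def _default_tree() -> dict:
    return {"c0": ["c1", "c2"], "c1": ["c3"], "c2": ["c4"]}


@dataclass
class SimConfig:
    """Generative settings for :func:`simulate_tree`.

    n_genes / cells_per_cluster
        Panel size and balanced cluster size (per sample).
    tree
        parent -> children edges over cluster ids; must be acyclic with the
        roots in ``root_clusters``.
    root_clusters
        Root (apex) clusters shared by both samples.
    ko_extra_roots
        Extra root-like clusters present only in the second sample.
    nb_dispersion
        Negative-binomial dispersion phi (var = mu + phi * mu^2).
    hub_fraction / alpha
        Fraction of genes boosted into connectome hubs, and the exponent
        linking root-program means to degree.
    transitional_boost
        Unspliced surplus factor for transitional clusters; 3 puts their
        expected velocity residual well clear of steady-state sampling noise.
    """

    n_genes: int = 800
    cells_per_cluster: int = 200
    tree: Mapping[str, Sequence[str]] = field(default_factory=_default_tree)
    root_clusters: Sequence[str] = ("c0",)
    samples: Sequence[str] = ("WT", "KO")
    ko_extra_roots: Sequence[str] = ("c5",)
    nb_dispersion: float = 0.5
    hub_fraction: float = 0.1
    alpha: float = 1.0
    transitional_boost: float = 3.0
    library_size: float = 2000.0
    n_markers: int = 40
    embedding_jitter: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.hub_fraction < 1.0:
            raise ValidationError("hub_fraction must be in (0, 1)")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not self.root_clusters:
            raise ValidationError("root_clusters must be non-empty")
        self._validate_tree()

    def _validate_tree(self) -> None:
        children = [c for kids in self.tree.values() for c in kids]
        if len(children) != len(set(children)):
            raise ValidationError("tree is not a tree: a cluster has two parents")
        nodes = set(self.tree) | set(children) | set(self.root_clusters)
        # cycle check: every non-root must be reachable from a root
        depth = self.depths()
        unreached = nodes - set(depth)
        if unreached:
            raise ValidationError(f"tree has unreachable or cyclic nodes: {sorted(unreached)}")

    def depths(self) -> dict:
        """BFS depth of every tree node from its root (roots at 0)."""
        depth = {r: 0 for r in self.root_clusters}
        frontier = list(self.root_clusters)
        while frontier:
            nxt = []
            for node in frontier:
                for child in self.tree.get(node, ()):  # leaves have no entry
                    if child in depth:
                        raise ValidationError(f"tree contains a cycle through {child!r}")
                    depth[child] = depth[node] + 1
                    nxt.append(child)
            frontier = nxt
        return depth

    def clusters_for_sample(self, sample) -> list:
        base = sorted(self.depths())
        if len(self.samples) > 1 and sample == self.samples[1]:
            return base + list(self.ko_extra_roots)
        return base


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    root_clusters: dict  # sample -> list of true root (apex) clusters
    pseudotime: pd.Series  # per cell, in [0, 1]
    steady_state: pd.Series  # per cell, True at attractor (root/leaf) regimes
    gamma: pd.Series  # per gene, generative splicing ratio


@dataclass
class SpatialSection:
    """A toy multi-clone spatial section over a gene subpanel."""

    profiles: pd.DataFrame  # units x panel genes, NB counts
    clone_labels: pd.Series  # unit -> clone id
    true_cluster: pd.Series  # unit -> generating cluster (ground truth)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterized by mean and dispersion (var = mu + phi mu^2)."""
    n = 1.0 / dispersion
    p = n / (n + np.maximum(mean, 1e-12))
    return rng.negative_binomial(n, p)


class _Programs:
    """Per-cluster mean expression programs shared by tree and spatial sims."""

    def __init__(self, cfg: SimConfig, rng: np.random.Generator):
        self.genes = pd.Index([f"g{i:04d}" for i in range(cfg.n_genes)])
        degrees = rng.lognormal(mean=0.0, sigma=1.0, size=cfg.n_genes)
        hubs = rng.choice(cfg.n_genes, size=max(1, int(cfg.hub_fraction * cfg.n_genes)), replace=False)
        degrees[hubs] *= 8.0
        self.degrees = pd.Series(degrees, index=self.genes, name="degree")

        root_prog = degrees**cfg.alpha
        self.root_program = root_prog / root_prog.sum()

        depth = cfg.depths()
        max_depth = max(max(depth.values()), 1)
        self.cluster_depth = {}
        self.programs = {}
        all_clusters = sorted(set(depth) | set(cfg.ko_extra_roots))
        for cl in all_clusters:
            d = depth.get(cl, 0)  # extra roots behave like depth-0 clusters
            self.cluster_depth[cl] = d
            marker_idx = rng.choice(cfg.n_genes, size=cfg.n_markers, replace=False)
            marker_prog = np.full(cfg.n_genes, 0.2 / cfg.n_genes)
            marker_prog[marker_idx] += 0.8 / cfg.n_markers
            marker_prog /= marker_prog.sum()
            if cl in cfg.root_clusters or cl in cfg.ko_extra_roots:
                # mostly the broad hub program, plus a small distinctive marker
                # flavour so distinct root clusters are not byte-identical states
                w_root = 0.85
            else:
                w_root = max(0.0, 1.0 - d / max_depth) * 0.8
            prog = w_root * self.root_program + (1.0 - w_root) * marker_prog
            self.programs[cl] = prog / prog.sum()

        self.gamma = pd.Series(
            rng.uniform(0.2, 1.0, size=cfg.n_genes), index=self.genes, name="gamma"
        )
        self.depth = depth
        self.max_depth = max_depth

    def is_steady(self, cluster, cfg: SimConfig) -> bool:
        # attractors: roots (incl. KO-unique) and leaves; internal clusters are in transit
        if cluster in cfg.root_clusters or cluster in cfg.ko_extra_roots:
            return True
        return cluster not in cfg.tree or not cfg.tree[cluster]


def _tree_layout(cfg: SimConfig, programs: _Programs) -> dict:
    """Deterministic 2-D positions: depth on y, siblings spread on x."""
    by_depth: dict[int, list] = {}
    for cl, d in sorted(programs.cluster_depth.items()):
        by_depth.setdefault(d, []).append(cl)
    pos = {}
    for d, nodes in by_depth.items():
        for i, cl in enumerate(sorted(nodes)):
            pos[cl] = (float(i) - (len(nodes) - 1) / 2.0, -float(d))
    return pos


def simulate_tree(cfg: SimConfig | None = None):
    """Generate (CountMatrixPair, cell table, degree vector, GroundTruth).

    The cell table has one block of ``cells_per_cluster`` cells per cluster
    per sample; the second sample additionally carries ``ko_extra_roots``.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    programs = _Programs(cfg, rng)
    layout = _tree_layout(cfg, programs)

    cell_rows = []
    spliced_blocks = []
    unspliced_blocks = []
    pseudotime = []
    steady_flags = []
    gamma = programs.gamma.to_numpy()

    for sample in cfg.samples:
        for cl in cfg.clusters_for_sample(sample):
            n = cfg.cells_per_cluster
            prog = programs.programs[cl]
            lib = cfg.library_size * rng.lognormal(0.0, 0.1, size=n)
            mean_s = lib[:, None] * prog[None, :]
            steady = programs.is_steady(cl, cfg)
            boost = 1.0 if steady else cfg.transitional_boost
            mean_u = boost * gamma[None, :] * mean_s
            spliced_blocks.append(_nb_sample(rng, mean_s, cfg.nb_dispersion))
            unspliced_blocks.append(_nb_sample(rng, mean_u, cfg.nb_dispersion))

            d = programs.cluster_depth[cl]
            pt = np.clip(
                d / programs.max_depth + rng.normal(0.0, 0.05, size=n), 0.0, 1.0
            )
            pseudotime.append(pt)
            steady_flags.append(np.full(n, steady))

            cx, cy = layout[cl]
            xy = rng.normal(loc=(cx, cy), scale=cfg.embedding_jitter, size=(n, 2))
            for i in range(n):
                cell_rows.append((sample, cl, xy[i, 0], xy[i, 1]))

    cell_ids = pd.Index([f"cell{i:05d}" for i in range(len(cell_rows))])
    cells = pd.DataFrame(cell_rows, columns=[SAMPLE, CLUSTER, "x", "y"], index=cell_ids)
    counts = CountMatrixPair(
        spliced=np.vstack(spliced_blocks),
        unspliced=np.vstack(unspliced_blocks),
        gene_ids=programs.genes,
        cell_ids=cell_ids,
    )
    truth = GroundTruth(
        root_clusters={
            s: list(cfg.root_clusters)
            + (list(cfg.ko_extra_roots) if len(cfg.samples) > 1 and s == cfg.samples[1] else [])
            for s in cfg.samples
        },
        pseudotime=pd.Series(np.concatenate(pseudotime), index=cell_ids, name="pseudotime"),
        steady_state=pd.Series(
            np.concatenate(steady_flags), index=cell_ids, name="steady_state"
        ),
        gamma=programs.gamma,
    )
    return counts, cells, programs.degrees, truth


def simulate_spatial(
    cfg: SimConfig,
    n_clones: int,
    cluster_mix: Mapping,
    seed: int,
    units_per_clone: int = 300,
    panel_size: int = 150,
) -> SpatialSection:
    """Toy spatial section: per clone, units sample a cluster from the clone's mix.

    ``cluster_mix`` maps clone id -> {cluster: proportion} (rows must sum to 1;
    clusters must exist in ``cfg``). Each unit draws NB counts from its
    cluster's mean program restricted to a ``panel_size``-gene subpanel (the
    genes most variable across cluster programs, so the panel is informative
    for label transfer). Deterministic given ``seed``.
    """
    prog_rng = np.random.default_rng(cfg.seed)  # programs must match simulate_tree
    programs = _Programs(cfg, prog_rng)
    clones = list(cluster_mix)
    if len(clones) != n_clones:
        raise ValidationError(f"cluster_mix has {len(clones)} clones, expected {n_clones}")
    known = set(programs.programs)
    for clone, mix in cluster_mix.items():
        unknown = set(mix) - known
        if unknown:
            raise ValidationError(f"clone {clone!r}: unknown clusters {sorted(unknown)}")
        total = float(sum(mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"clone {clone!r}: mix sums to {total}, must sum to 1")

    prog_mat = np.vstack([programs.programs[c] for c in sorted(programs.programs)])
    panel_idx = np.argsort(prog_mat.var(axis=0))[::-1][:panel_size]
    panel_idx = np.sort(panel_idx)
    panel = programs.genes[panel_idx]

    rng = np.random.default_rng(seed)
    rows, clone_col, cluster_col = [], [], []
    for clone in clones:
        mix = cluster_mix[clone]
        keys = sorted(mix)
        probs = np.array([mix[k] for k in keys], dtype=float)
        draws = rng.choice(len(keys), size=units_per_clone, p=probs / probs.sum())
        for d in draws:
            cl = keys[d]
            sub = programs.programs[cl][panel_idx]
            mean = 500.0 * sub / sub.sum()
            rows.append(_nb_sample(rng, mean, cfg.nb_dispersion))
            clone_col.append(clone)
            cluster_col.append(cl)
    unit_ids = pd.Index([f"unit{i:05d}" for i in range(len(rows))])
    return SpatialSection(
        profiles=pd.DataFrame(np.vstack(rows), index=unit_ids, columns=panel),
        clone_labels=pd.Series(clone_col, index=unit_ids, name="clone"),
        true_cluster=pd.Series(cluster_col, index=unit_ids, name="cluster"),
    )
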