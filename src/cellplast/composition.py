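"""Cluster composition, gene-set module scores and cell-cycle phase calls.

Composition analysis counts each cluster per sample and compares the
proportions between two conditions. Gene-set scoring follows the standard
binned-control scheme: each set gene is compared against control genes drawn
from the same mean-expression bin, which removes depth/abundance trends from
the score. Cell-cycle assignment applies that score to user-supplied S-phase
and G2/M gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import CLUSTER, SAMPLE
from .exceptions import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "ScoreConfig",
    "cluster_proportions",
    "proportion_difference",
    "gene_set_score",
    "assign_cell_cycle",
]


@dataclass
class ScoreConfig:
    """Binned-control scoring parameters (ecosystem defaults; sampling is seeded)."""

    n_bins: int = 25
    n_ctrl_per_bin: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 1 or self.n_ctrl_per_bin < 1:
            raise ValidationError("n_bins and n_ctrl_per_bin must be >= 1")


def cluster_proportions(cells: pd.DataFrame) -> pd.DataFrame:
    """Count and proportion of every cluster within each sample.

    The cluster universe is the union over samples; clusters absent from a
    sample appear with count 0. Per-sample proportions sum to 1.
    """
    if cells.empty:
        raise ValidationError("cell table is empty")
    counts = (
        cells.groupby([SAMPLE, CLUSTER], sort=True, observed=True)
        .size()
        .unstack(fill_value=0)
        .stack()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(SAMPLE)["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts.set_index([SAMPLE, CLUSTER])


def proportion_difference(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster proportion change between two single-sample composition tables.

    ``a`` and ``b`` are outputs of :func:`cluster_proportions` restricted to one
    sample each (or plain tables indexed by cluster with a ``proportion``
    column). Missing clusters count as 0; delta = b - a, which sums to 0 over
    the union. ``fold`` is b/a with division-by-zero flagged as +inf and 0/0
    as NaN (``fold_defined`` False).
    """

    def _prop(t: pd.DataFrame) -> pd.Series:
        p = t["proportion"]
        if isinstance(p.index, pd.MultiIndex):
            samples = p.index.get_level_values(0).unique()
            if len(samples) != 1:
                raise ValidationError(
                    "pass a single-sample composition table (one sample per side)"
                )
            p = p.droplevel(0)
        return p

    pa, pb = _prop(a), _prop(b)
    universe = pa.index.union(pb.index)
    pa = pa.reindex(universe, fill_value=0.0)
    pb = pb.reindex(universe, fill_value=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(pa > 0, pb / np.maximum(pa, 1e-300), np.where(pb > 0, np.inf, np.nan))
    return pd.DataFrame(
        {
            "proportion_a": pa,
            "proportion_b": pb,
            "delta": pb - pa,
            "fold": fold,
            "fold_defined": (pa > 0),
        }
    )


def _bin_assignments(mean_expr: pd.Series, n_bins: int) -> np.ndarray:
    """Split genes into n_bins nearly equal-size bins by mean expression rank.

    Genes are ordered by (mean, gene id) — the id breaks ties deterministically —
    and the ordering is cut into contiguous bins.
    """
    order = np.lexsort((np.asarray(mean_expr.index, dtype=object), mean_expr.to_numpy()))
    bins = np.empty(len(mean_expr), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    return bins


def gene_set_score(
    expr: ExpressionMatrix, gene_set, cfg: ScoreConfig | None = None
) -> pd.Series:
    """Mean set expression minus mean expression of bin-matched control genes.

    For every expression bin containing at least one set gene,
    ``n_ctrl_per_bin`` control genes are drawn from that bin without
    replacement (the whole bin if it is smaller), using a generator seeded
    with ``cfg.seed``. score_i = mean(expr_i over set) - mean(expr_i over
    controls). Raises if no set gene is present, listing the missing ones.
    """
    cfg = cfg or ScoreConfig()
    gene_set = pd.Index(pd.unique(pd.Series(list(gene_set)).astype(str)))
    present = gene_set.intersection(expr.gene_ids)
    if len(present) == 0:
        raise ValidationError(
            f"no gene of the set is in the expression panel; missing: {list(gene_set)[:10]}"
        )
    mean_expr = pd.Series(expr.values.mean(axis=0), index=expr.gene_ids)
    bins = _bin_assignments(mean_expr, cfg.n_bins)
    set_pos = expr.gene_ids.get_indexer(present)
    set_bins = np.unique(bins[set_pos])

    rng = np.random.default_rng(cfg.seed)
    ctrl_pos: list[np.ndarray] = []
    for b in set_bins:
        pool = np.flatnonzero(bins == b)
        take = min(cfg.n_ctrl_per_bin, len(pool))
        ctrl_pos.append(rng.choice(pool, size=take, replace=False))
    ctrl = np.unique(np.concatenate(ctrl_pos))

    score = expr.values[:, set_pos].mean(axis=1) - expr.values[:, ctrl].mean(axis=1)
    out = pd.Series(score, index=expr.cell_ids, name="score")
    out.attrs["n_set_genes"] = int(len(present))
    out.attrs["n_ctrl_genes"] = int(len(ctrl))
    return out


def assign_cell_cycle(
    expr: ExpressionMatrix, s_genes, g2m_genes, cfg: ScoreConfig | None = None
) -> pd.DataFrame:
    """Per-cell phase in {G1, S, G2M} from binned-control S and G2/M scores.

    A cell is G1 when both scores are negative; otherwise the larger score
    wins, with exact ties broken toward S.
    """
    cfg = cfg or ScoreConfig()
    s_present = pd.Index(pd.Series(list(s_genes)).astype(str)).intersection(expr.gene_ids)
    g2m_present = pd.Index(pd.Series(list(g2m_genes)).astype(str)).intersection(expr.gene_ids)
    if len(s_present) == 0 and len(g2m_present) == 0:
        raise ValidationError("neither the S nor the G2/M gene list overlaps the panel")
    s_score = gene_set_score(expr, s_genes, cfg)
    g2m_score = gene_set_score(expr, g2m_genes, cfg)
    phase = np.where(
        (s_score < 0) & (g2m_score < 0),
        "G1",
        np.where(s_score.to_numpy() >= g2m_score.to_numpy(), "S", "G2M"),
    )
    return pd.DataFrame(
        {"s_score": s_score, "g2m_score": g2m_score, "phase": phase}, index=expr.cell_ids
    )
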