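"""Label transfer from scRNA-seq clusters onto spatial expression profiles.

Each spatial unit (a segmented cell or bin from an in-situ panel) is assigned
the scRNA-seq cluster whose centroid profile maximizes the Spearman rank
correlation over the genes shared between the spatial panel and the
dissociated reference. Assignments are retained only when the best
correlation strictly exceeds a threshold (default 0.5); everything else is
flagged unassigned. Per-clone composition of the retained assignments
summarizes intratumoral heterogeneity as cluster richness and Shannon
entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cells import CLUSTER, SAMPLE, validate_cell_table
from .exceptions import ValidationError
from .io import ExpressionMatrix

__all__ = [
    "MappingConfig",
    "cluster_centroids",
    "map_spatial_to_clusters",
    "clone_composition",
]


@dataclass
class MappingConfig:
    """rho_min: strict retention threshold; min_shared_genes: panel-overlap floor."""

    rho_min: float = 0.5
    min_shared_genes: int = 50

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_min <= 1.0:
            raise ValidationError("rho_min must lie in [-1, 1]")


def cluster_centroids(expr: ExpressionMatrix, cells: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean of normalized log expression (clusters x genes).

    Clusters are pooled across samples; pass a single-sample cell table to get
    sample-specific centroids.
    """
    cells = validate_cell_table(cells)
    missing = cells.index.difference(expr.cell_ids)
    if len(missing):
        raise ValidationError(f"cells absent from expression matrix: {list(missing)[:5]}")
    mat = pd.DataFrame(
        expr.values[expr.cell_ids.get_indexer(cells.index)],
        index=cells.index,
        columns=expr.gene_ids,
    )
    centroids = mat.groupby(cells[CLUSTER]).mean()
    if (centroids.isna()).any().any():  # pragma: no cover - groupby can't produce this
        raise ValidationError("empty cluster encountered")
    centroids.index.name = CLUSTER
    return centroids


def map_spatial_to_clusters(
    profiles: pd.DataFrame,
    centroids: pd.DataFrame,
    cfg: MappingConfig | None = None,
) -> pd.DataFrame:
    """Spearman-correlate each spatial unit against every cluster centroid.

    ``profiles`` is units x genes. Correlations use average ranks over the
    shared gene panel; the best cluster (ties -> lowest cluster id) is
    retained iff its rho strictly exceeds ``cfg.rho_min``. Returns a
    DataFrame indexed by unit with columns best_cluster (None when not
    retained), rho, retained.
    """
    cfg = cfg or MappingConfig()
    shared = profiles.columns.intersection(centroids.columns)
    if len(shared) < cfg.min_shared_genes:
        raise ValidationError(
            f"only {len(shared)} genes shared between spatial panel and centroids "
            f"(need >= {cfg.min_shared_genes})"
        )
    p = profiles[shared].to_numpy(float)
    c = centroids[shared].to_numpy(float)
    pr = rankdata(p, axis=1)
    cr = rankdata(c, axis=1)

    def _center_norm(m):
        mc = m - m.mean(axis=1, keepdims=True)
        ss = np.sqrt((mc**2).sum(axis=1))
        return mc, ss

    pc, pss = _center_norm(pr)
    cc, css = _center_norm(cr)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (pc @ cc.T) / np.outer(pss, css)  # units x clusters
    rho = np.where(np.isfinite(rho), rho, -np.inf)  # constant-rank profile: no correlation

    # argmax with lowest-cluster-id tie-break: centroids sorted by id first
    order = np.argsort(np.asarray(centroids.index, dtype=object))
    rho_sorted = rho[:, order]
    best_pos = rho_sorted.argmax(axis=1)
    best_rho = rho_sorted[np.arange(len(p)), best_pos]
    best_cluster = np.asarray(centroids.index, dtype=object)[order][best_pos]
    retained = best_rho > cfg.rho_min
    out = pd.DataFrame(
        {
            "best_cluster": np.where(retained, best_cluster, None),
            "rho": np.where(np.isfinite(best_rho), best_rho, np.nan),
            "retained": retained,
        },
        index=profiles.index,
    )
    out.attrs["n_shared_genes"] = int(len(shared))
    return out


def clone_composition(mapping: pd.DataFrame, clone_labels: pd.Series) -> pd.DataFrame:
    """Cluster composition per clone over retained units.

    Returns one row per (clone, cluster) with count and proportion, plus the
    per-clone summary in ``.attrs['summary']``: n_retained, richness (distinct
    clusters) and Shannon entropy in nats. Clones with no retained units are
    flagged with richness 0 and NaN entropy.
    """
    clone_labels = clone_labels.reindex(mapping.index)
    if clone_labels.isna().any():
        raise ValidationError("clone labels do not cover every mapped unit")
    kept = mapping[mapping["retained"]]
    rows = []
    summary = []
    for clone in pd.unique(clone_labels):
        units = kept.loc[clone_labels.reindex(kept.index) == clone]
        if units.empty:
            summary.append({"clone": clone, "n_retained": 0, "richness": 0, "entropy": np.nan})
            continue
        counts = units["best_cluster"].value_counts()
        props = counts / counts.sum()
        for cl, n in counts.items():
            rows.append(
                {"clone": clone, CLUSTER: cl, "count": int(n), "proportion": props[cl]}
            )
        p = props.to_numpy(float)
        entropy = float(-(p * np.log(p)).sum())
        summary.append(
            {
                "clone": clone,
                "n_retained": int(counts.sum()),
                "richness": int(len(counts)),
                "entropy": entropy,
            }
        )
    out = pd.DataFrame(rows, columns=["clone", CLUSTER, "count", "proportion"])
    out.attrs["summary"] = pd.DataFrame(summary).set_index("clone")
    return out
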