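"""Per-cell transcriptome-connectome correlation (CCAT) entropy.

CCAT approximates signalling entropy — a proxy for differentiation potency —
by the Pearson correlation between a cell's normalized log expression profile
and the protein-interaction-network degree of each gene. Cells whose
transcriptome is broadly loaded onto network hubs score high; cells dominated
by narrow peripheral programs score near zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ExpressionMatrix

__all__ = ["read_degree_table", "map_gene_ids", "compute_ccat"]

log = logging.getLogger(__name__)


def read_degree_table(path) -> pd.Series:
    """Read a two-column TSV (gene_id, degree) into a degree Series."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: expected columns gene_id, degree")
    s = pd.Series(df.iloc[:, 1].to_numpy(float), index=df.iloc[:, 0].astype(str))
    _validate_degrees(s)
    return s


def _validate_degrees(degrees: pd.Series) -> pd.Series:
    degrees = pd.Series(degrees, dtype=float)
    degrees.index = degrees.index.astype(str)
    if degrees.index.has_duplicates:
        raise ValidationError("degree table has duplicate gene ids")
    if (degrees <= 0).any() or not np.isfinite(degrees).all():
        raise ValidationError("connectome degrees must be positive and finite")
    return degrees


def map_gene_ids(degrees: pd.Series, ortholog_map: pd.DataFrame) -> pd.Series:
    """Relabel a degree table through a two-column ortholog table.

    ``ortholog_map`` columns: source id (matching ``degrees``), target id
    (matching the expression panel). Many-to-one collisions keep the maximum
    degree; unmapped genes are dropped.
    """
    src = ortholog_map.iloc[:, 0].astype(str)
    dst = ortholog_map.iloc[:, 1].astype(str)
    mapped = degrees.reindex(src)
    mapped.index = dst
    mapped = mapped.dropna().groupby(level=0).max()
    return _validate_degrees(mapped)


def compute_ccat(expr: ExpressionMatrix, degrees: pd.Series) -> pd.Series:
    """Pearson correlation of each cell's expression with connectome degree.

    The gene universe is the intersection of the expression panel and the
    degree table (at least 3 genes). Cells with zero expression variance over
    the shared genes get NaN and are excluded from downstream medians rather
    than imputed as zero. The returned Series carries the shared-gene count in
    ``.attrs["n_shared_genes"]``.
    """
    degrees = _validate_degrees(pd.Series(degrees))
    shared = expr.gene_ids.intersection(degrees.index)
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} genes shared between expression and degree table (need >= 3)"
        )
    if len(shared) < len(expr.gene_ids):
        log.info(
            "CCAT gene universe: %d of %d expression genes have a degree",
            len(shared),
            len(expr.gene_ids),
        )

    cols = expr.gene_ids.get_indexer(shared)
    x = expr.values[:, cols]  # cells x shared
    d = degrees.loc[shared].to_numpy(float)

    xc = x - x.mean(axis=1, keepdims=True)
    dc = d - d.mean()
    x_ss = (xc**2).sum(axis=1)
    d_ss = float((dc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ dc) / np.sqrt(x_ss * d_ss)
    r[x_ss == 0] = np.nan
    r = np.clip(r, -1.0, 1.0)  # guard rounding just past the bounds

    out = pd.Series(r, index=expr.cell_ids, name="ccat")
    out.attrs["n_shared_genes"] = int(len(shared))
    return out
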