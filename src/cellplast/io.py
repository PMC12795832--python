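"""Reading, validation, QC filtering and normalization of spliced/unspliced counts.

The on-disk contract is MatrixMarket matrices (cells x genes) with one-id-per-line
TSV sidecars, or a single HDF5 container with ``layers/spliced``,
``layers/unspliced``, ``genes`` and ``cells`` datasets. In memory the pair of
layers lives in a :class:`CountMatrixPair`, which enforces that both layers share
one cells x genes grid with unique identifiers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .exceptions import EmptyResultError, FormatError, ValidationError

__all__ = [
    "CountMatrixPair",
    "ExpressionMatrix",
    "QCConfig",
    "QCReport",
    "read_counts",
    "read_counts_h5",
    "write_counts",
    "write_counts_h5",
    "qc_filter",
    "normalize_log",
]


def _as_dense_counts(mat, name: str) -> np.ndarray:
    if sparse.issparse(mat):
        mat = mat.toarray()
    arr = np.asarray(mat)
    if arr.ndim != 2:
        raise ValidationError(f"{name}: expected a 2-D matrix, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError(f"{name}: counts must be integers")
        arr = np.round(arr)
    arr = arr.astype(np.int64, copy=False)
    if (arr < 0).any():
        raise ValidationError(f"{name}: counts must be nonnegative")
    return arr


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dupes = ids[ids.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")


@dataclass
class CountMatrixPair:
    """Spliced and unspliced counts on one shared cells x genes grid.

    Both layers are dense int64 arrays; construction validates shape agreement,
    nonnegativity and identifier uniqueness.
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.spliced = _as_dense_counts(self.spliced, "spliced")
        self.unspliced = _as_dense_counts(self.unspliced, "unspliced")
        self.gene_ids = pd.Index(self.gene_ids).astype(str)
        self.cell_ids = pd.Index(self.cell_ids).astype(str)
        if self.spliced.shape != self.unspliced.shape:
            raise ValidationError(
                "spliced and unspliced shapes differ: "
                f"{self.spliced.shape} vs {self.unspliced.shape}"
            )
        n_cells, n_genes = self.spliced.shape
        if len(self.cell_ids) != n_cells:
            raise ValidationError(
                f"{n_cells} matrix rows but {len(self.cell_ids)} cell ids"
            )
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"{n_genes} matrix columns but {len(self.gene_ids)} gene ids"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    def subset(self, cell_mask=None, gene_mask=None) -> "CountMatrixPair":
        """Subset both layers identically; order is preserved."""
        cm = slice(None) if cell_mask is None else np.asarray(cell_mask)
        gm = slice(None) if gene_mask is None else np.asarray(gene_mask)
        return CountMatrixPair(
            spliced=self.spliced[cm][:, gm],
            unspliced=self.unspliced[cm][:, gm],
            gene_ids=self.gene_ids[gm],
            cell_ids=self.cell_ids[cm],
        )


@dataclass
class ExpressionMatrix:
    """Depth-normalized, log1p-transformed expression (cells x genes)."""

    values: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = pd.Index(self.gene_ids).astype(str)
        self.cell_ids = pd.Index(self.cell_ids).astype(str)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("expression shape disagrees with identifiers")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression values must be finite")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class QCConfig:
    """Cell/gene filtering thresholds.

    Cells with fewer than ``min_genes_per_cell`` detected genes (count > 0) or a
    mitochondrial read fraction above ``max_mito_fraction`` are removed; genes
    then detected in fewer than ``min_cells_per_gene`` of the remaining cells are
    removed. Both cell rules use strict inequalities on the "remove" side, so a
    cell with exactly ``min_genes_per_cell`` genes is retained.
    """

    min_genes_per_cell: int = 100
    max_mito_fraction: float = 0.20
    min_cells_per_gene: int = 20
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if self.min_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ValidationError("QC count thresholds must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValidationError("max_mito_fraction must be within [0, 1]")


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    n_cells_removed_genes: int
    n_cells_removed_mito: int
    n_genes_removed: int
    n_cells_out: int
    n_genes_out: int


def _read_id_file(path) -> pd.Index:
    # one identifier per line; extra TAB-separated columns are ignored
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return pd.Index(ids)


def read_counts(spliced_path, unspliced_path, genes_path, cells_path) -> CountMatrixPair:
    """Read a MatrixMarket spliced/unspliced pair with TSV id sidecars.

    Matrices are cells x genes. Raises :class:`FormatError` naming the
    offending file on any dimension mismatch.
    """
    try:
        spliced = spio.mmread(spliced_path)
        unspliced = spio.mmread(unspliced_path)
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"could not parse MatrixMarket input: {exc}") from exc
    genes = _read_id_file(genes_path)
    cells = _read_id_file(cells_path)
    for name, mat in (("spliced", spliced), ("unspliced", unspliced)):
        path = spliced_path if name == "spliced" else unspliced_path
        if mat.shape[0] != len(cells):
            raise FormatError(
                f"{path}: {mat.shape[0]} rows but {len(cells)} cell ids in {cells_path}"
            )
        if mat.shape[1] != len(genes):
            raise FormatError(
                f"{path}: {mat.shape[1]} columns but {len(genes)} gene ids in {genes_path}"
            )
    if spliced.shape != unspliced.shape:
        raise FormatError(
            f"{unspliced_path}: shape {unspliced.shape} does not match "
            f"spliced shape {spliced.shape}"
        )
    return CountMatrixPair(spliced, unspliced, genes, cells)


def write_counts(pair: CountMatrixPair, out_dir) -> None:
    """Write the MTX + TSV sidecar layout that :func:`read_counts` reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "spliced.mtx", sparse.coo_matrix(pair.spliced))
    spio.mmwrite(out / "unspliced.mtx", sparse.coo_matrix(pair.unspliced))
    (out / "genes.tsv").write_text("\n".join(pair.gene_ids) + "\n")
    (out / "cells.tsv").write_text("\n".join(pair.cell_ids) + "\n")


def read_counts_h5(path) -> CountMatrixPair:
    """Read a single HDF5 container with layers/spliced, layers/unspliced, genes, cells."""
    with h5py.File(path, "r") as f:
        try:
            spliced = f["layers/spliced"][...]
            unspliced = f["layers/unspliced"][...]
            genes = [g.decode() if isinstance(g, bytes) else g for g in f["genes"][...]]
            cells = [c.decode() if isinstance(c, bytes) else c for c in f["cells"][...]]
        except KeyError as exc:
            raise FormatError(f"{path}: missing dataset {exc}") from exc
    if spliced.shape[0] != len(cells) or spliced.shape[1] != len(genes):
        raise FormatError(f"{path}: layer shape disagrees with genes/cells datasets")
    return CountMatrixPair(spliced, unspliced, pd.Index(genes), pd.Index(cells))


def write_counts_h5(pair: CountMatrixPair, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("layers/spliced", data=pair.spliced)
        f.create_dataset("layers/unspliced", data=pair.unspliced)
        f.create_dataset("genes", data=np.array(pair.gene_ids, dtype="S"))
        f.create_dataset("cells", data=np.array(pair.cell_ids, dtype="S"))


def qc_filter(counts: CountMatrixPair, cfg: QCConfig | None = None) -> CountMatrixPair:
    """Remove low-complexity / high-mitochondrial cells, then rarely detected genes.

    All masks are computed on the spliced layer; the unspliced layer is subset
    identically. The returned pair carries a :class:`QCReport` in ``.qc_report``.
    Idempotent: reapplying the same config changes nothing.
    """
    cfg = cfg or QCConfig()
    s = counts.spliced
    genes_per_cell = (s > 0).sum(axis=1)
    totals = s.sum(axis=1)
    mito_mask = np.array(
        [g.lower().startswith(cfg.mito_prefix.lower()) for g in counts.gene_ids]
    )
    mito_counts = s[:, mito_mask].sum(axis=1) if mito_mask.any() else np.zeros(len(totals))
    with np.errstate(divide="ignore", invalid="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1), 0.0)

    low_genes = genes_per_cell < cfg.min_genes_per_cell
    high_mito = mito_frac > cfg.max_mito_fraction
    keep_cells = ~(low_genes | high_mito)
    if not keep_cells.any():
        raise EmptyResultError(
            f"QC removed all {counts.n_cells} cells "
            f"({int(low_genes.sum())} below {cfg.min_genes_per_cell} genes, "
            f"{int(high_mito.sum())} above {cfg.max_mito_fraction:.0%} mito)"
        )

    detected_in = (s[keep_cells] > 0).sum(axis=0)
    keep_genes = detected_in >= cfg.min_cells_per_gene

    out = counts.subset(cell_mask=keep_cells, gene_mask=keep_genes)
    out.qc_report = QCReport(
        n_cells_in=counts.n_cells,
        n_genes_in=counts.n_genes,
        n_cells_removed_genes=int(low_genes.sum()),
        n_cells_removed_mito=int((high_mito & ~low_genes).sum()),
        n_genes_removed=int((~keep_genes).sum()),
        n_cells_out=out.n_cells,
        n_genes_out=out.n_genes,
    )
    return out


def normalize_log(counts: CountMatrixPair, target_sum: float = 10_000.0) -> ExpressionMatrix:
    """Depth-normalize spliced counts to ``target_sum`` per cell, then log1p.

    Deterministic; depth-invariant (scaling a cell's counts by any positive
    constant leaves its output unchanged). Cells with zero total count are a
    hard error — run :func:`qc_filter` first.
    """
    totals = counts.spliced.sum(axis=1).astype(float)
    if (totals == 0).any():
        bad = counts.cell_ids[totals == 0].tolist()[:5]
        raise ValidationError(
            f"cells with zero total count (e.g. {bad}); apply qc_filter before normalizing"
        )
    scaled = counts.spliced * (target_sum / totals)[:, None]
    return ExpressionMatrix(np.log1p(scaled), counts.gene_ids, counts.cell_ids)
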