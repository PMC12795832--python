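"""The per-cell annotation table and its contract.

A cell table is a pandas DataFrame indexed by unique cell id with columns
``sample`` (sample id), ``cluster`` (cluster id) and embedding coordinates
``x``, ``y`` (optionally ``z``). Embeddings are trajectory-preserving
coordinates (e.g. PHATE) computed upstream; this package consumes them as
plain numbers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

SAMPLE = "sample"
CLUSTER = "cluster"
EMBEDDING_COLS = ("x", "y", "z")

__all__ = ["SAMPLE", "CLUSTER", "validate_cell_table", "embedding_columns", "embedding_matrix"]


def embedding_columns(cells: pd.DataFrame) -> list[str]:
    cols = [c for c in EMBEDDING_COLS if c in cells.columns]
    if len(cols) < 2:
        raise ValidationError("cell table needs at least 2 embedding columns ('x', 'y')")
    return cols


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Check the cell-table contract; returns the table with string index."""
    for col in (SAMPLE, CLUSTER):
        if col not in cells.columns:
            raise ValidationError(f"cell table is missing required column {col!r}")
        if cells[col].isna().any():
            raise ValidationError(f"cell table column {col!r} contains missing values")
    cols = embedding_columns(cells)
    coords = cells[cols].to_numpy(float)
    if not np.isfinite(coords).all():
        raise ValidationError("cell table embedding coordinates must be finite")
    if cells.index.has_duplicates:
        raise ValidationError("cell table index (cell ids) has duplicates")
    out = cells.copy()
    out.index = out.index.astype(str)
    return out


def embedding_matrix(cells: pd.DataFrame) -> np.ndarray:
    return cells[embedding_columns(cells)].to_numpy(float)
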