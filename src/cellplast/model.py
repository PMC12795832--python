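"""Model/Results interface tying the pipeline together.

``CellPlasticity`` is constructed from a spliced/unspliced count pair, the
per-cell annotation table (sample, cluster, embedding) and a gene-wise
connectome degree vector; ``fit()`` runs normalization, per-cell CCAT
entropy, steady-state velocity lengths, within-cluster centrality and the
Valley/Ridge/VR combination, returning a :class:`CellPlasticityResults` that
carries every intermediate quantity plus apex rankings, landscape grids and a
printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import centrality as _centrality
from . import entropy as _entropy
from . import landscape as _landscape
from . import velocity as _velocity
from .cells import CLUSTER, SAMPLE, validate_cell_table
from .centrality import CentralityConfig
from .exceptions import ValidationError
from .io import CountMatrixPair, ExpressionMatrix, QCConfig, normalize_log, qc_filter
from .landscape import ApexRanking, LandscapeGrid, VRConfig
from .velocity import VelocityConfig

__all__ = ["CellPlasticity", "CellPlasticityResults"]


class CellPlasticity:
    """Cell-plastic-potential (valley-ridge) model for a two-sample experiment.

    Parameters
    ----------
    counts
        Spliced/unspliced counts. Apply :func:`cellplast.io.qc_filter`
        beforehand, or pass ``qc`` to have the model do it.
    cells
        Cell table (index = cell id; columns sample, cluster, x, y[, z]).
        Must cover exactly the cells in ``counts`` (after QC).
    degrees
        Gene -> connectome degree, on (a superset of) the count panel.
    """

    def __init__(
        self,
        counts: CountMatrixPair,
        cells: pd.DataFrame,
        degrees: pd.Series,
        *,
        qc: QCConfig | None = None,
        vr_config: VRConfig | None = None,
        velocity_config: VelocityConfig | None = None,
        centrality_config: CentralityConfig | None = None,
        target_sum: float = 10_000.0,
    ):
        if qc is not None:
            counts = qc_filter(counts, qc)
        cells = validate_cell_table(cells)
        cells = cells.loc[cells.index.intersection(counts.cell_ids)]
        missing = pd.Index(counts.cell_ids).difference(cells.index)
        if len(missing):
            raise ValidationError(
                f"cell table missing annotations for {len(missing)} cells "
                f"(e.g. {list(missing)[:3]})"
            )
        # keep the count ordering as the canonical one
        self.counts = counts
        self.cells = cells.reindex(counts.cell_ids)
        self.degrees = pd.Series(degrees, dtype=float)
        self.vr_config = vr_config or VRConfig()
        self.velocity_config = velocity_config or VelocityConfig()
        self.centrality_config = centrality_config or CentralityConfig()
        self.target_sum = target_sum

    @classmethod
    def from_directory(cls, path, degrees_path, cells_path=None, **kwargs):
        """Build from the MTX/TSV layout written by ``cellplast simulate``."""
        from .io import read_counts

        path = Path(path)
        counts = read_counts(
            path / "spliced.mtx", path / "unspliced.mtx", path / "genes.tsv", path / "cells.tsv"
        )
        cells = pd.read_csv(cells_path or path / "cell_table.tsv", sep="\t", index_col=0)
        degrees = _entropy.read_degree_table(degrees_path)
        return cls(counts, cells, degrees, **kwargs)

    def fit(self) -> "CellPlasticityResults":
        expr = normalize_log(self.counts, self.target_sum)
        ccat = _entropy.compute_ccat(expr, self.degrees)
        gamma = _velocity.fit_gamma(self.counts, self.velocity_config)
        vel = _velocity.velocity_lengths(self.counts, gamma)
        cent = _centrality.centrality_distance(self.cells, self.centrality_config)
        valley = _landscape.valley_component(ccat, self.cells)
        ridge = _landscape.ridge_component(vel.length, cent, self.cells, self.vr_config)
        n_cells = self.cells.groupby([SAMPLE, CLUSTER], sort=False).size()
        vr = _landscape.vr_score(valley, ridge, self.vr_config, n_cells=n_cells)
        return CellPlasticityResults(
            model=self, expr=expr, ccat=ccat, velocity=vel, centrality=cent, vr_table=vr
        )


@dataclass
class CellPlasticityResults:
    """Fitted quantities of a :class:`CellPlasticity` model."""

    model: CellPlasticity
    expr: ExpressionMatrix
    ccat: pd.Series
    velocity: "_velocity.VelocityResult"
    centrality: pd.DataFrame
    vr_table: pd.DataFrame

    def rank_apexes(self, samples=None) -> ApexRanking:
        return _landscape.rank_apexes(self.vr_table, samples)

    def landscape(self, sample=None, resolution: int = 64, bandwidth=None) -> LandscapeGrid:
        return _landscape.landscape_grid(
            self.model.cells, self.vr_table, resolution=resolution,
            bandwidth=bandwidth, sample=sample,
        )

    def plot_landscape(self, sample=None, resolution: int = 64, bandwidth=None, ax=None):
        """Filled-contour preview of the landscape grid (matplotlib)."""
        import matplotlib.pyplot as plt

        grid = self.landscape(sample=sample, resolution=resolution, bandwidth=bandwidth)
        if ax is None:
            _, ax = plt.subplots()
        xmin, xmax, ymin, ymax = grid.extent
        m = ax.contourf(
            np.linspace(xmin, xmax, grid.heights.shape[1]),
            np.linspace(ymin, ymax, grid.heights.shape[0]),
            grid.heights,
            levels=20,
        )
        ax.figure.colorbar(m, ax=ax, label="VR score")
        ax.set_xlabel("embedding x")
        ax.set_ylabel("embedding y")
        return ax

    def summary(self) -> str:
        """Readable per-(sample, cluster) table plus apex calls."""
        lines = ["Cell plastic potential (valley-ridge) fit", "=" * 42]
        cfg = self.model.vr_config
        lines.append(
            f"weights: valley={cfg.w_valley} ridge={cfg.w_ridge}  "
            f"scaling={cfg.scaling_scope}  cells={len(self.model.cells)}  "
            f"genes={self.model.counts.n_genes}"
        )
        tab = self.vr_table.copy()
        tab["apex_rank"] = tab.groupby(level=0)["vr"].rank(ascending=False).astype(int)
        lines.append(tab.round(4).to_string())
        for s, ranked in self.rank_apexes().ranking.items():
            lines.append(f"apexes[{s}]: {' > '.join(map(str, ranked))}")
        return "\n".join(lines)
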