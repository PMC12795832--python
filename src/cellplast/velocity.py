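"""Steady-state RNA-velocity lengths from spliced/unspliced counts.

The splicing ratio gamma of each gene is fitted by least squares through the
origin, u = gamma * s, on the cells in the upper tail of total (s + u)
abundance — the usual steady-state approximation, where high-expression cells
are assumed to sit at transcriptional equilibrium. The per-cell velocity
residual v = u - gamma * s is near zero at attractor states and large for
cells in transit between states; its L2 norm over fitted genes is the
"velocity length" consumed by the Ridge component of the VR score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import EmptyResultError, ValidationError
from .io import CountMatrixPair

__all__ = ["VelocityConfig", "VelocityResult", "fit_gamma", "velocity_lengths"]


@dataclass
class VelocityConfig:
    """Fit-regime selector.

    extreme_quantile
        Fraction of cells (by total s+u for the gene, upper tail, inclusive
        threshold at the 1-q quantile) used for the steady-state fit.
    min_counts
        Genes whose total s+u over all cells falls below this are excluded.
    """

    extreme_quantile: float = 0.05
    min_counts: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.extreme_quantile <= 0.5:
            raise ValidationError("extreme_quantile must be in (0, 0.5]")


@dataclass
class VelocityResult:
    """Fitted gammas (NaN = excluded gene), velocity residual matrix and lengths."""

    gamma: pd.Series
    velocity: pd.DataFrame  # cells x fitted genes
    length: pd.Series


def fit_gamma(counts: CountMatrixPair, cfg: VelocityConfig | None = None) -> pd.Series:
    """Per-gene steady-state splicing ratio gamma.

    For each gene: take cells whose s+u is at or above the (1 - extreme_quantile)
    quantile; gamma = sum(u*s) / sum(s^2) over that subset, clipped at 0.
    Genes with sum(s^2) == 0 on the subset or total counts below
    ``cfg.min_counts`` are excluded (NaN).
    """
    cfg = cfg or VelocityConfig()
    s = counts.spliced.astype(float)
    u = counts.unspliced.astype(float)
    total = s + u

    # upper-tail mask, per gene, inclusive threshold
    thresh = np.quantile(total, 1.0 - cfg.extreme_quantile, axis=0)
    mask = total >= thresh[None, :]

    num = (u * s * mask).sum(axis=0)
    den = (s * s * mask).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
    gamma = np.clip(gamma, 0.0, None)
    gamma[total.sum(axis=0) < cfg.min_counts] = np.nan

    out = pd.Series(gamma, index=counts.gene_ids, name="gamma")
    if out.isna().all():
        raise EmptyResultError("no fittable genes (all excluded by min_counts or zero spliced)")
    return out


def velocity_lengths(counts: CountMatrixPair, gamma: pd.Series) -> VelocityResult:
    """Velocity residuals v = u - gamma*s over fitted genes and their L2 norms."""
    gamma = gamma.reindex(counts.gene_ids)
    fitted = gamma.notna().to_numpy()
    if not fitted.any():
        raise EmptyResultError("gamma is missing for every gene")
    g = gamma.to_numpy(float)[fitted]
    s = counts.spliced[:, fitted].astype(float)
    u = counts.unspliced[:, fitted].astype(float)
    v = u - g[None, :] * s
    length = np.sqrt((v**2).sum(axis=1))
    return VelocityResult(
        gamma=gamma,
        velocity=pd.DataFrame(v, index=counts.cell_ids, columns=counts.gene_ids[fitted]),
        length=pd.Series(length, index=counts.cell_ids, name="velocity_length"),
    )
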