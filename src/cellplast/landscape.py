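"""Valley-Ridge (VR) scoring and Waddington-like landscape grids.

Per (sample, cluster) group the score combines two components:

* **Valley** — the median per-cell transcriptome-connectome entropy (CCAT) of
  the group; high for plastic, progenitor-like populations.
* **Ridge** — the product of (i) the group median of [0,1]-scaled inverse
  velocity lengths and (ii) the group median of [0,1]-scaled within-cluster
  centrality distances; high for slow-moving cells sitting away from a
  cluster core, i.e. saddle/ridge regions of the landscape.

VR = w_valley * Valley + w_ridge * Ridge with default weights 0.9 and 0.1.
Clusters with the highest VR are the landscape apexes — the candidate root
(origin) populations of the differentiation trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cells import CLUSTER, SAMPLE, embedding_columns, validate_cell_table
from .exceptions import ValidationError

__all__ = [
    "VRConfig",
    "LandscapeGrid",
    "ApexRanking",
    "scale_unit",
    "valley_component",
    "ridge_component",
    "vr_score",
    "landscape_grid",
    "rank_apexes",
]


@dataclass
class VRConfig:
    """Weights and scaling scope for the VR score.

    scaling_scope
        "global": inverse velocities (and their L=0 caps) are min-max scaled
        across all cells of all samples jointly, keeping VR comparable across
        samples; "per_sample" scales within each sample.
    ridge_aggregation
        "product_of_medians" (default): median(scaled 1/L) * median(scaled D)
        per group; "median_of_products" takes the group median of the per-cell
        products instead.
    """

    w_valley: float = 0.9
    w_ridge: float = 0.1
    scaling_scope: Literal["global", "per_sample"] = "global"
    ridge_aggregation: Literal["product_of_medians", "median_of_products"] = (
        "product_of_medians"
    )

    def __post_init__(self) -> None:
        if self.w_valley < 0 or self.w_ridge < 0:
            raise ValidationError("VR weights must be >= 0")
        if self.scaling_scope not in ("global", "per_sample"):
            raise ValidationError('scaling_scope must be "global" or "per_sample"')


def scale_unit(x) -> np.ndarray:
    """Min-max scale a finite vector to [0, 1]; a constant vector maps to all 0."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot scale an empty vector")
    if not np.isfinite(x).all():
        raise ValidationError("scale_unit requires finite values (cap infinities first)")
    span = x.max() - x.min()
    if span == 0:
        return np.zeros_like(x)
    return (x - x.min()) / span


def _group_keys(cells: pd.DataFrame) -> pd.MultiIndex:
    return pd.MultiIndex.from_frame(cells[[SAMPLE, CLUSTER]].drop_duplicates())


def valley_component(ccat: pd.Series, cells: pd.DataFrame) -> pd.Series:
    """Median defined CCAT per (sample, cluster); all-NaN groups stay NaN (missing)."""
    cells = validate_cell_table(cells)
    ccat = ccat.reindex(cells.index)
    valley = (
        pd.DataFrame({SAMPLE: cells[SAMPLE], CLUSTER: cells[CLUSTER], "ccat": ccat})
        .groupby([SAMPLE, CLUSTER], sort=False)["ccat"]
        .median()  # NaN entries are excluded; all-NaN group -> NaN
    )
    valley.name = "valley"
    return valley


def _scaled_inverse_velocity(length: pd.Series, cells: pd.DataFrame, cfg: VRConfig) -> pd.Series:
    """1/L per cell, L=0 capped at the max finite inverse in scope, then unit-scaled."""
    length = length.reindex(cells.index).to_numpy(float)
    if np.isnan(length).any():
        raise ValidationError("velocity length missing for some cells in the table")
    with np.errstate(divide="ignore"):
        inv = np.where(length > 0, 1.0 / np.maximum(length, 1e-300), np.inf)
    out = np.empty_like(inv)
    scopes = (
        [np.ones(len(cells), dtype=bool)]
        if cfg.scaling_scope == "global"
        else [(cells[SAMPLE] == s).to_numpy() for s in cells[SAMPLE].unique()]
    )
    for m in scopes:
        v = inv[m]
        finite = np.isfinite(v)
        if finite.any():
            v = np.where(finite, v, v[finite].max())
        else:  # every length is 0 in this scope
            v = np.zeros_like(v)
        out[m] = scale_unit(v)
    return pd.Series(out, index=cells.index, name="scaled_inverse_velocity")


def ridge_component(
    length: pd.Series,
    centrality: pd.DataFrame,
    cells: pd.DataFrame,
    cfg: VRConfig | None = None,
) -> pd.Series:
    """Ridge score per (sample, cluster) from velocity lengths and centrality.

    ``length`` is the per-cell velocity length; ``centrality`` must provide a
    ``scaled_distance`` column indexed by cell id (see
    :func:`cellplast.centrality.centrality_distance`). Result lies in [0, 1].
    """
    cfg = cfg or VRConfig()
    cells = validate_cell_table(cells)
    scaled_inv = _scaled_inverse_velocity(length, cells, cfg)
    scaled_dist = centrality["scaled_distance"].reindex(cells.index)
    if scaled_dist.isna().any():
        raise ValidationError("centrality table does not cover every cell")
    df = pd.DataFrame(
        {
            SAMPLE: cells[SAMPLE],
            CLUSTER: cells[CLUSTER],
            "siv": scaled_inv,
            "sd": scaled_dist,
        }
    )
    grouped = df.groupby([SAMPLE, CLUSTER], sort=False)
    if cfg.ridge_aggregation == "median_of_products":
        ridge = grouped.apply(lambda g: (g["siv"] * g["sd"]).median(), include_groups=False)
    else:
        med = grouped[["siv", "sd"]].median()
        ridge = med["siv"] * med["sd"]
    ridge.name = "ridge"
    return ridge


def vr_score(
    valley: pd.Series | float,
    ridge: pd.Series | float,
    cfg: VRConfig | None = None,
    n_cells: pd.Series | None = None,
) -> pd.DataFrame | float:
    """Weighted sum VR = w_valley*valley + w_ridge*ridge.

    Scalar inputs return a scalar. Series inputs (indexed by (sample, cluster))
    must share keys; orphans on either side raise a :class:`ValidationError`
    listing them.
    """
    cfg = cfg or VRConfig()
    if np.isscalar(valley) and np.isscalar(ridge):
        return cfg.w_valley * float(valley) + cfg.w_ridge * float(ridge)
    valley = pd.Series(valley)
    ridge = pd.Series(ridge)
    only_v = valley.index.difference(ridge.index)
    only_r = ridge.index.difference(valley.index)
    if len(only_v) or len(only_r):
        raise ValidationError(
            f"valley/ridge group keys differ; valley-only={list(only_v)}, "
            f"ridge-only={list(only_r)}"
        )
    ridge = ridge.reindex(valley.index)
    out = pd.DataFrame(
        {
            "valley": valley,
            "ridge": ridge,
            "vr": cfg.w_valley * valley + cfg.w_ridge * ridge,
        }
    )
    if n_cells is not None:
        out.insert(0, "n_cells", pd.Series(n_cells).reindex(valley.index).astype("Int64"))
    out.index.names = [SAMPLE, CLUSTER]
    return out


@dataclass
class LandscapeGrid:
    """A rasterized Waddington-like surface over the 2-D embedding.

    heights[i, j] is the Gaussian-kernel weighted mean VR of cells around grid
    point (x_j, y_i); empty zones fall back to the scope minimum VR so they
    render as low ground.
    """

    heights: np.ndarray
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    bandwidth: float
    apexes: dict = field(default_factory=dict)  # sample -> ranked cluster list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.heights)


def landscape_grid(
    cells: pd.DataFrame,
    vr: pd.DataFrame,
    resolution: int = 64,
    bandwidth: float | None = None,
    sample: str | None = None,
) -> LandscapeGrid:
    """Rasterize per-cell VR (each cell carries its group's score) onto a grid.

    ``vr`` is the table from :func:`vr_score`. With ``sample`` given, only that
    sample's cells are used. Bandwidth defaults to 5% of the embedding
    diagonal. Deterministic.
    """
    cells = validate_cell_table(cells)
    if sample is not None:
        cells = cells[cells[SAMPLE] == sample]
        if cells.empty:
            raise ValidationError(f"unknown sample id {sample!r}")
    cols = embedding_columns(cells)
    if len(cols) != 2:
        raise ValidationError(
            "landscape_grid needs a 2-D embedding; project 3-D coordinates first"
        )
    keys = pd.MultiIndex.from_frame(cells[[SAMPLE, CLUSTER]])
    cell_vr = vr["vr"].reindex(keys).to_numpy(float)
    if np.isnan(cell_vr).any():
        raise ValidationError("VR table does not cover every (sample, cluster) in the cells")
    xy = cells[cols].to_numpy(float)
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    pad_x = 0.05 * max(xmax - xmin, 1e-12)
    pad_y = 0.05 * max(ymax - ymin, 1e-12)
    xmin, xmax, ymin, ymax = xmin - pad_x, xmax + pad_x, ymin - pad_y, ymax + pad_y
    if bandwidth is None:
        bandwidth = 0.05 * float(np.hypot(xmax - xmin, ymax - ymin))
    gx = np.linspace(xmin, xmax, resolution)
    gy = np.linspace(ymin, ymax, resolution)
    gxx, gyy = np.meshgrid(gx, gy)
    pts = np.column_stack([gxx.ravel(), gyy.ravel()])
    d2 = ((pts[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * bandwidth**2))
    wsum = w.sum(axis=1)
    heights = np.full(len(pts), np.nanmin(cell_vr))
    ok = wsum > 1e-12
    heights[ok] = (w[ok] @ cell_vr) / wsum[ok]
    apexes = {
        s: list(vr.loc[s].sort_values("vr", ascending=False).index)
        for s in vr.index.get_level_values(0).unique()
    }
    return LandscapeGrid(
        heights=heights.reshape(resolution, resolution),
        extent=(xmin, xmax, ymin, ymax),
        bandwidth=float(bandwidth),
        apexes=apexes,
    )


@dataclass
class ApexRanking:
    """Apex (root-candidate) ranking per sample plus cross-sample differences."""

    ranking: dict  # sample -> clusters ordered by VR descending
    delta: pd.DataFrame  # shared clusters: vr/valley per sample + differences
    unique: dict  # sample -> clusters absent from the other sample


def rank_apexes(vr: pd.DataFrame, samples: Sequence | None = None) -> ApexRanking:
    """Rank clusters by VR per sample and difference shared clusters across a pair.

    ``delta`` columns: vr_<a>, vr_<b>, delta_vr (= b - a), and the analogous
    valley (median CCAT) columns, since the cross-sample "Δentropy" reading of
    the landscape can be taken on either quantity.
    """
    all_samples = list(vr.index.get_level_values(0).unique())
    if samples is None:
        samples = all_samples
    for s in samples:
        if s not in all_samples:
            raise ValidationError(f"unknown sample id {s!r}; have {all_samples}")
    ranking = {
        s: list(vr.loc[s].sort_values("vr", ascending=False).index) for s in samples
    }
    if len(samples) != 2:
        return ApexRanking(ranking=ranking, delta=pd.DataFrame(), unique={})
    a, b = samples
    ca = vr.loc[a]
    cb = vr.loc[b]
    shared = ca.index.intersection(cb.index)
    delta = pd.DataFrame(
        {
            f"vr_{a}": ca.loc[shared, "vr"],
            f"vr_{b}": cb.loc[shared, "vr"],
            "delta_vr": cb.loc[shared, "vr"] - ca.loc[shared, "vr"],
            f"valley_{a}": ca.loc[shared, "valley"],
            f"valley_{b}": cb.loc[shared, "valley"],
            "delta_valley": cb.loc[shared, "valley"] - ca.loc[shared, "valley"],
        }
    )
    unique = {
        a: list(ca.index.difference(cb.index)),
        b: list(cb.index.difference(ca.index)),
    }
    return ApexRanking(ranking=ranking, delta=delta, unique=unique)
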