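"""Covariate layers for migratory habitat selection.

Four layers enter the selection model: standardized terrain ruggedness
(vector ruggedness measure, VRM), a major-river indicator, categorical land
cover with open ground as the reference class, and an exponential
distance-decay representation of road influence, ``exp(-alpha / d)`` with
``d`` the distance to the nearest road in km.  All layers are aggregated to
a common analysis grain (1 km by default) and co-registered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .raster import RasterGrid
from .synthetic import LandscapeBundle
from .vector import distance_grid, rasterize_lines

__all__ = [
    "CovariateStack",
    "vector_ruggedness",
    "road_decay",
    "decay_from_distance",
    "standardize",
    "aggregate",
    "build_stack",
]

LANDCOVER_CLASSES = {0: "open", 1: "dense", 2: "burned", 3: "coastal"}


def _horn_gradient(z: np.ndarray, cell_m: float) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 finite-difference slope components dz/dx, dz/dy (m/m).

    Border rows/columns come out NaN (the kernel would extend past the
    raster edge).
    """
    p = np.full_like(z, np.nan)
    q = np.full_like(z, np.nan)
    p[1:-1, 1:-1] = (
        (z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:])
        - (z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2])
    ) / (8 * cell_m)
    q[1:-1, 1:-1] = (
        (z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:])
        - (z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:])
    ) / (8 * cell_m)
    return p, q


def unit_normals(elevation: RasterGrid) -> np.ndarray:
    """Per-cell unit surface-normal vectors, shape (3, nrows, ncols).

    The normal of the plane fitted through a cell is ``(-p, -q, 1)``
    normalised, with (p, q) the Horn slope components; flat cells get
    (0, 0, 1) so aspect is never undefined.
    """
    cell_m = elevation.cell_size * 1000.0
    z = np.where(elevation.valid, elevation.data, np.nan)
    p, q = _horn_gradient(z, cell_m)
    norm = np.sqrt(1.0 + p**2 + q**2)
    return np.stack([-p / norm, -q / norm, 1.0 / norm])


def vector_ruggedness(elevation: RasterGrid, window: int = 3) -> RasterGrid:
    """Vector ruggedness measure in [0, 1].

    Sums the unit surface normals over a ``window x window`` neighbourhood
    and returns ``1 - |R| / n`` where ``|R|`` is the resultant magnitude and
    ``n = window**2``.  Flat or uniformly tilted terrain gives 0 (all
    normals parallel); maximally dispersed normals approach 1.  Cells whose
    kernel or window reaches past the raster edge (or touches nodata) are
    nodata in the output.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if min(elevation.shape) < 3:
        raise ValueError("elevation must be at least 3x3")
    normals = unit_normals(elevation)
    half = window // 2
    n = window * window
    sums = np.zeros_like(normals)
    for dr in range(-half, half + 1):
        for dc in range(-half, half + 1):
            shifted = np.full_like(normals, np.nan)
            rs = slice(max(dr, 0), normals.shape[1] + min(dr, 0))
            rd = slice(max(-dr, 0), normals.shape[1] + min(-dr, 0))
            cs = slice(max(dc, 0), normals.shape[2] + min(dc, 0))
            cd = slice(max(-dc, 0), normals.shape[2] + min(-dc, 0))
            shifted[:, rd, cd] = normals[:, rs, cs]
            sums += shifted  # NaN propagates: incomplete windows -> nodata
    resultant = np.sqrt((sums**2).sum(axis=0))
    vrm = 1.0 - resultant / n
    return elevation.like(np.clip(vrm, 0.0, 1.0))


def decay_from_distance(distance_km: np.ndarray, alpha: float) -> np.ndarray:
    """Exponential road decay ``exp(-alpha/d)``; defined as 0 at d = 0."""
    if alpha <= 0:
        raise ValueError("alpha must be positive (km)")
    d = np.asarray(distance_km, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.exp(-alpha / np.where(d > 0, d, np.inf))
    return np.where(d > 0, out, np.where(np.isnan(d), np.nan, 0.0))


def road_decay(roads, grid: RasterGrid, alpha: float) -> RasterGrid:
    """Road distance-decay layer in [0, 1) on ``grid``."""
    if not roads:
        raise ValueError("road decay undefined for an empty road set")
    d = distance_grid(roads, grid)
    return grid.like(decay_from_distance(d.data, alpha))


def standardize(grid: RasterGrid) -> RasterGrid:
    """Centre and scale to unit variance over valid cells."""
    v = grid.data[grid.valid]
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant layer")
    return grid.like((grid.data - v.mean()) / sd)


def aggregate(grid: RasterGrid, factor: int, how: str = "mean") -> RasterGrid:
    """Block-aggregate by an integer factor.

    ``how``: "mean" for continuous layers, "mode" for categorical classes,
    "any" for presence indicators (any-touch).  Blocks containing only
    nodata come out nodata; partial blocks at the south/east edges are
    dropped.
    """
    if factor == 1:
        return grid.copy()
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr = grid.nrows // factor
    nc = grid.ncols // factor
    blocks = grid.data[: nr * factor, : nc * factor].reshape(nr, factor, nc, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(nr, nc, factor * factor)
    valid_counts = np.isfinite(blocks).sum(axis=2)
    with np.errstate(invalid="ignore"):
        if how == "mean":
            out = np.nanmean(np.where(np.isfinite(blocks), blocks, np.nan), axis=2)
        elif how == "any":
            out = np.nanmax(np.where(np.isfinite(blocks), blocks, np.nan), axis=2)
            out = (out > 0).astype(float)
        elif how == "mode":
            out = np.zeros((nr, nc))
            for r in range(nr):
                for c in range(nc):
                    vals = blocks[r, c][np.isfinite(blocks[r, c])]
                    if len(vals):
                        uniq, cnt = np.unique(vals, return_counts=True)
                        out[r, c] = uniq[np.argmax(cnt)]
        else:
            raise ValueError(f"unknown aggregation rule {how!r}")
    out = np.where(valid_counts > 0, out, np.nan)
    # y0 shifts if trailing rows are dropped: kept block rows start at the top
    new_y0 = grid.y0 + (grid.nrows - nr * factor) * grid.cell_size
    return RasterGrid(
        out, x0=grid.x0, y0=new_y0, cell_size=grid.cell_size * factor, crs=grid.crs
    )


@dataclass
class CovariateStack:
    """Co-registered covariate layers at the analysis grain.

    ``road_distance_km`` is kept alongside the decay layer so the decay
    parameter can be re-evaluated (the alpha scan) without recomputing
    distances.
    """

    ruggedness_z: RasterGrid
    river: RasterGrid
    landcover: RasterGrid
    road_decay: RasterGrid
    road_distance_km: RasterGrid
    alpha: float
    grain: float = 1.0

    def __post_init__(self) -> None:
        for name in ("river", "landcover", "road_decay", "road_distance_km"):
            if not self.ruggedness_z.same_grid(getattr(self, name)):
                raise ValueError(f"layer {name} not co-registered with ruggedness_z")
        rd = self.road_decay.data[self.road_decay.valid]
        if len(rd) and (rd.min() < 0 or rd.max() >= 1):
            raise ValueError("road_decay must lie in [0, 1)")

    @property
    def grid(self) -> RasterGrid:
        return self.ruggedness_z

    def with_alpha(self, alpha: float) -> "CovariateStack":
        decay = self.road_decay.like(
            decay_from_distance(self.road_distance_km.data, alpha)
        )
        return replace(self, road_decay=decay, alpha=alpha)

    def covariates_at(self, x, y) -> pd.DataFrame:
        """Covariate values at point locations (containing-cell lookup)."""
        row, col = self.grid.xy_to_rowcol(np.asarray(x), np.asarray(y))
        row = np.clip(row, 0, self.grid.nrows - 1)
        col = np.clip(col, 0, self.grid.ncols - 1)
        lc = self.landcover.data[row, col]
        return pd.DataFrame(
            {
                "ruggedness": self.ruggedness_z.data[row, col],
                "river": self.river.data[row, col],
                "road_decay": self.road_decay.data[row, col],
                "road_distance_km": self.road_distance_km.data[row, col],
                "dense": (lc == 1).astype(float),
                "burned": (lc == 2).astype(float),
                "coastal": (lc == 3).astype(float),
            }
        )


def build_stack(
    bundle: LandscapeBundle,
    alpha: float,
    grain: float = 1.0,
    roads=None,
) -> CovariateStack:
    """Assemble the covariate stack from a landscape bundle.

    Ruggedness and road distance are computed at the native cell size and
    block-aggregated to ``grain`` (mean), land cover by modal class, rivers
    by any-touch; ruggedness is standardized after aggregation.  ``roads``
    defaults to the bundle's existing roads; pass a combined list to build a
    stack that includes proposed roads.
    """
    native = bundle.cell_size
    if grain < native:
        raise ValueError("grain must be at least the native cell size")
    factor = grain / native
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError("grain must be an integer multiple of the native cell size")
    factor = int(round(factor))
    roads = list(bundle.roads_existing) if roads is None else list(roads)
    if not roads:
        raise ValueError("road decay undefined for an empty road set")

    vrm = vector_ruggedness(bundle.elevation)
    ruggedness_z = standardize(aggregate(vrm, factor, "mean"))
    river = aggregate(rasterize_lines(bundle.rivers, bundle.elevation), factor, "any")
    landcover = aggregate(bundle.landcover, factor, "mode")
    dist = aggregate(distance_grid(roads, bundle.elevation), factor, "mean")
    decay = dist.like(decay_from_distance(dist.data, alpha))
    return CovariateStack(
        ruggedness_z=ruggedness_z,
        river=river,
        landcover=landcover,
        road_decay=decay,
        road_distance_km=dist,
        alpha=alpha,
        grain=grain,
    )
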