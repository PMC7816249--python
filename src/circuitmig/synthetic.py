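"""Synthetic landscapes and migration tracks.

Downstream stages assume telemetry with a residency-migration-residency NSD
shape over a landscape of smooth terrain, linear river/road features, and
categorical land cover with an "open" reference class.  This module builds
such inputs from a single seeded generator so the whole pipeline is testable
end to end without any real data products.

Movement is a discrete-time biased random walk on the raster lattice
(8-neighbour steps): at each step the walker weights neighbouring cells by
``(1/resistance)**selection_strength`` times a directional bias toward its
current goal (home range centre during residency, destination region during
migration).  This is deliberately the same family of random walker whose
expected net passage the circuit stage computes, so corridor-recovery
experiments are exact to the cell.  Fixes are reported at cell centres every
``fix_interval_h`` hours and subsample the walk: the animal takes
``steps_per_fix`` lattice steps between consecutive fixes, since a collar
records positions far less often than an animal chooses movements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point

from .migration import TelemetryTrack
from .raster import RasterGrid

__all__ = ["SimulationConfig", "LandscapeBundle", "generate_landscape", "simulate_tracks"]

Rect = tuple[float, float, float, float]  # xmin, ymin, xmax, ymax


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study system.

    Durations are in fix counts (8-h fixes by default, mirroring collar
    schedules for long-distance ungulate telemetry).  ``selection_strength``
    scales how strongly walkers prefer low-resistance cells (0 = blind walk);
    ``goal_bias`` scales the directional pull toward the destination.
    """

    seed: int = 0
    n_animals: int = 30
    years_per_animal: int = 1
    season: str = "fall"
    fix_interval_h: float = 8.0
    steps_per_fix: int = 4
    residency_duration: int = 30
    migration_max_steps: int = 4000
    selection_strength: float = 1.0
    goal_bias: float = 1.5
    residency_bias: float = 2.0
    start_region: Rect = (5.0, 5.0, 35.0, 25.0)
    end_region: Rect = (65.0, 75.0, 95.0, 95.0)
    # landscape structure
    terrain_relief_m: float = 300.0
    terrain_smoothness_cells: float = 4.0
    n_rivers: int = 2
    n_roads: int = 1
    n_communities: int = 4
    coast_width_km: float = 3.0

    def __post_init__(self) -> None:
        if self.residency_duration < 2:
            raise ValueError("residency_duration must be at least 2 fixes")
        if self.steps_per_fix < 1:
            raise ValueError("steps_per_fix must be >= 1")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.fix_interval_h <= 0:
            raise ValueError("fix_interval_h must be positive")


@dataclass
class LandscapeBundle:
    """Co-registered synthetic landscape layers.

    Land-cover codes: 0 open (reference class), 1 dense vegetation,
    2 burned, 3 coastal water.
    """

    elevation: RasterGrid
    landcover: RasterGrid
    rivers: list[LineString]
    roads_existing: list[LineString]
    roads_proposed: list[LineString]
    communities: dict[str, Point]
    extent: Rect
    cell_size: float

    def __post_init__(self) -> None:
        if not self.elevation.same_grid(self.landcover):
            raise ValueError("elevation and landcover must share the grid")
        classes = np.unique(self.landcover.data[self.landcover.valid])
        if not np.isin(classes, [0, 1, 2, 3]).all():
            raise ValueError("landcover values must be in {0, 1, 2, 3}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _crossing_line(
    rng: np.random.Generator, extent: Rect, axis: str, n_vertices: int = 24
) -> LineString:
    """Wiggly polyline crossing the full extent along one axis."""
    xmin, ymin, xmax, ymax = extent
    if axis == "x":  # west-east
        xs = np.linspace(xmin, xmax, n_vertices)
        base = rng.uniform(ymin + 0.15 * (ymax - ymin), ymax - 0.15 * (ymax - ymin))
        wig = np.cumsum(rng.normal(0, (ymax - ymin) / 40, n_vertices))
        ys = np.clip(base + wig - wig.mean(), ymin, ymax - 1e-9)
    else:  # south-north
        ys = np.linspace(ymin, ymax, n_vertices)
        base = rng.uniform(xmin + 0.15 * (xmax - xmin), xmax - 0.15 * (xmax - xmin))
        wig = np.cumsum(rng.normal(0, (xmax - xmin) / 40, n_vertices))
        xs = np.clip(base + wig - wig.mean(), xmin, xmax - 1e-9)
    return LineString(np.column_stack([xs, ys]))


def generate_landscape(
    config: SimulationConfig,
    extent: Rect = (0.0, 0.0, 100.0, 100.0),
    cell_size: float = 1.0,
) -> LandscapeBundle:
    """Build a seeded synthetic landscape bundle.

    Elevation is a smoothed random field whose amplitude itself varies
    smoothly in space, so terrain ruggedness has both rough and gentle
    districts.  Rivers and roads are wiggly polylines crossing the extent;
    land cover is carved out of further smooth fields with open (class 0)
    the most frequent class and a coastal strip along the western edge.
    """
    xmin, ymin, xmax, ymax = extent
    ncols = int(round((xmax - xmin) / cell_size))
    nrows = int(round((ymax - ymin) / cell_size))
    if nrows < 20 or ncols < 20:
        raise ValueError("extent must span at least 20x20 cells")
    rng = np.random.default_rng(config.seed)
    shape = (nrows, ncols)

    base = _smooth_field(rng, shape, config.terrain_smoothness_cells)
    envelope = _smooth_field(rng, shape, 4 * config.terrain_smoothness_cells)
    envelope = (envelope - envelope.min()) / max(np.ptp(envelope), 1e-12)
    elev_data = config.terrain_relief_m * base * (0.25 + 0.75 * envelope)
    if config.terrain_relief_m == 0:
        elev_data = np.zeros(shape)
    elevation = RasterGrid(elev_data, x0=xmin, y0=ymin, cell_size=cell_size)

    veg = _smooth_field(rng, shape, 3.0)
    burn = _smooth_field(rng, shape, 5.0)
    lc = np.zeros(shape)
    lc[veg > np.quantile(veg, 0.75)] = 1.0  # dense vegetation
    lc[burn > np.quantile(burn, 0.93)] = 2.0  # burn scars override
    xs, _ = elevation.cell_centers()
    lc[xs - xmin < config.coast_width_km] = 3.0  # coastal strip, west edge
    landcover = elevation.like(lc)

    rivers = [_crossing_line(rng, extent, "x") for _ in range(config.n_rivers)]
    roads_existing = [_crossing_line(rng, extent, "y") for _ in range(config.n_roads)]
    # one proposed road crossing the middle of the extent, west-east
    mid = (ymin + ymax) / 2.0
    n_vert = 16
    px = np.linspace(xmin, xmax, n_vert)
    py = mid + np.cumsum(rng.normal(0, (ymax - ymin) / 60, n_vert))
    py = np.clip(py - py.mean() + mid, ymin, ymax - 1e-9)
    roads_proposed = [LineString(np.column_stack([px, py]))]

    communities = {}
    for i in range(config.n_communities):
        cx = rng.uniform(xmin + 0.1 * (xmax - xmin), xmax - 0.1 * (xmax - xmin))
        cy = rng.uniform(ymin + 0.1 * (ymax - ymin), ymax - 0.1 * (ymax - ymin))
        communities[f"community_{i + 1}"] = Point(cx, cy)

    return LandscapeBundle(
        elevation=elevation,
        landcover=landcover,
        rivers=rivers,
        roads_existing=roads_existing,
        roads_proposed=roads_proposed,
        communities=communities,
        extent=extent,
        cell_size=cell_size,
    )


# -- movement simulation -------------------------------------------------

_NBR = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
)
_NBR_DIST = np.hypot(_NBR[:, 0], _NBR[:, 1])


class UnreachableDestinationError(RuntimeError):
    """End region cannot be reached over finite-resistance cells."""


def _region_mask(grid: RasterGrid, region: Rect) -> np.ndarray:
    xs, ys = grid.cell_centers()
    xmin, ymin, xmax, ymax = region
    return (xs >= xmin) & (xs < xmax) & (ys >= ymin) & (ys < ymax)


def _region_cells(grid: RasterGrid, region: Rect, ok: np.ndarray) -> np.ndarray:
    xs, ys = grid.cell_centers()
    xmin, ymin, xmax, ymax = region
    inside = (xs >= xmin) & (xs < xmax) & (ys >= ymin) & (ys < ymax) & ok
    cells = np.argwhere(inside)
    if len(cells) == 0:
        raise ValueError(f"region {region} contains no traversable cells")
    return cells


def _walk(
    rng: np.random.Generator,
    inv_r_pow: np.ndarray,
    ok: np.ndarray,
    start: tuple[int, int],
    target_xy: tuple[float, float],
    grid: RasterGrid,
    bias: float,
    n_steps: int | None,
    stop_region: Rect | None,
    max_steps: int,
) -> list[tuple[int, int]]:
    """Biased lattice walk; returns visited cells (one per fix)."""
    nrows, ncols = ok.shape
    path = [start]
    r, c = start
    tx, ty = target_xy
    steps = 0
    while True:
        if n_steps is not None and steps >= n_steps:
            break
        if stop_region is not None:
            x, y = grid.rowcol_to_xy(r, c)
            sxmin, symin, sxmax, symax = stop_region
            if sxmin <= x < sxmax and symin <= y < symax:
                break
            if steps >= max_steps:
                raise RuntimeError(
                    f"walker failed to reach destination within {max_steps} steps"
                )
        rr = r + _NBR[:, 0]
        cc = c + _NBR[:, 1]
        inb = (rr >= 0) & (rr < nrows) & (cc >= 0) & (cc < ncols)
        rr, cc, dist = rr[inb], cc[inb], _NBR_DIST[inb]
        valid = ok[rr, cc]
        rr, cc, dist = rr[valid], cc[valid], dist[valid]
        if len(rr) == 0:
            raise RuntimeError("walker trapped: no traversable neighbour")
        w = inv_r_pow[rr, cc].astype(float)
        if bias > 0:
            x, y = grid.rowcol_to_xy(r, c)
            xn, yn = grid.rowcol_to_xy(rr, cc)
            d_cur = np.hypot(tx - x, ty - y)
            d_new = np.hypot(tx - xn, ty - yn)
            # progress toward target per unit step length, in [-1, 1]
            progress = (d_cur - d_new) / (dist * grid.cell_size)
            # directional persistence grows as the migration drags on, so a
            # walker cannot stall indefinitely in a low-resistance pocket
            ramp = 1.0 + steps / 400.0 if stop_region is not None else 1.0
            w = w * np.exp(bias * ramp * progress)
        w = w / w.sum()
        k = rng.choice(len(rr), p=w)
        r, c = int(rr[k]), int(cc[k])
        path.append((r, c))
        steps += 1
    return path


_SEASON_START = {"fall": "-09-01", "spring": "-04-01"}


def simulate_tracks(
    bundle: LandscapeBundle,
    resistance: RasterGrid,
    config: SimulationConfig,
) -> list[TelemetryTrack]:
    """Simulate seasonal migration tracks over a resistance surface.

    Each track is residency near ``start_region``, a biased walk to
    ``end_region`` preferring low-resistance cells, then residency at the
    destination, sampled every ``fix_interval_h`` hours.  Raises
    :class:`UnreachableDestinationError` when no finite-resistance path
    links the two regions.
    """
    grid = resistance
    ok = grid.valid & (grid.data > 0) & np.isfinite(grid.data)
    if not ok.any():
        raise ValueError("resistance surface has no traversable cells")
    if (grid.data[grid.valid] <= 0).any():
        raise ValueError("resistance must be strictly positive on valid cells")

    labels, _ = ndimage.label(ok, structure=np.ones((3, 3)))
    start_cells = _region_cells(grid, config.start_region, ok)
    end_cells = _region_cells(grid, config.end_region, ok)
    start_labels = set(labels[tuple(start_cells.T)])
    end_labels = set(labels[tuple(end_cells.T)])
    common = start_labels & end_labels
    if not common:
        raise UnreachableDestinationError(
            "no finite-resistance path connects start_region to end_region"
        )
    comp_ok = np.isin(labels, sorted(common)) & ok

    inv_r_pow = np.zeros_like(grid.data)
    inv_r_pow[ok] = (1.0 / grid.data[ok]) ** config.selection_strength

    rng = np.random.default_rng(config.seed)
    sfx = _SEASON_START.get(config.season, "-01-01")
    tracks: list[TelemetryTrack] = []
    for a in range(config.n_animals):
        for y in range(config.years_per_animal):
            year = 2020 + y
            # start cell drawn from traversable start-region cells
            cand = start_cells[comp_ok[tuple(start_cells.T)]]
            home = tuple(cand[rng.integers(len(cand))])
            home_xy = grid.rowcol_to_xy(*home)
            ecand = end_cells[comp_ok[tuple(end_cells.T)]]
            goal = tuple(ecand[rng.integers(len(ecand))])
            goal_xy = grid.rowcol_to_xy(*goal)

            spf = config.steps_per_fix
            # residency walks stay within their seasonal range
            start_ok = comp_ok & _region_mask(grid, config.start_region)
            end_ok = comp_ok & _region_mask(grid, config.end_region)
            res1 = _walk(
                rng, inv_r_pow, start_ok, home, home_xy, grid,
                config.residency_bias, (config.residency_duration - 1) * spf, None, 0,
            )
            mig = _walk(
                rng, inv_r_pow, comp_ok, res1[-1], goal_xy, grid,
                config.goal_bias, None, config.end_region, config.migration_max_steps,
            )
            arrive_xy = grid.rowcol_to_xy(*mig[-1])
            res2 = _walk(
                rng, inv_r_pow, end_ok, mig[-1], arrive_xy, grid,
                config.residency_bias, config.residency_duration * spf, None, 0,
            )
            full = res1 + mig[1:] + res2[1:]
            cells = full[::spf]
            if (len(full) - 1) % spf:
                cells = cells + [full[-1]]
            cells = np.array(cells)
            xs, ys = grid.rowcol_to_xy(cells[:, 0], cells[:, 1])
            t0 = pd.Timestamp(f"{year}{sfx}")
            times = t0 + pd.to_timedelta(
                np.arange(len(cells)) * config.fix_interval_h, unit="h"
            )
            tracks.append(
                TelemetryTrack(
                    animal_id=f"animal_{a + 1:03d}",
                    season=config.season,
                    year=year,
                    timestamps=pd.DatetimeIndex(times),
                    fixes=np.column_stack([xs, ys]),
                )
            )
    return tracks
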