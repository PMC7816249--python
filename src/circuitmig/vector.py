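"""Vector features (road/river polylines, community points) and GeoJSON I/O.

Geometry lives in shapely; this module only adds the thin label/IO layer the
pipeline needs.  Coordinates are projected kilometres throughout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, MultiLineString, Point, mapping, shape
from shapely.ops import unary_union

from .raster import RasterGrid

__all__ = [
    "lines_from_arrays",
    "merge_lines",
    "read_geojson_lines",
    "write_geojson_lines",
    "read_geojson_points",
    "write_geojson_points",
    "rasterize_lines",
    "distance_grid",
]


def lines_from_arrays(arrays) -> list[LineString]:
    """Build LineStrings from (n, 2) coordinate arrays."""
    return [LineString(np.asarray(a, dtype=float)) for a in arrays]


def merge_lines(*line_sets) -> list[LineString]:
    """Concatenate several polyline collections into one flat list."""
    out: list[LineString] = []
    for ls in line_sets:
        out.extend(ls)
    return out


def write_geojson_lines(lines, path: str | Path, names=None) -> None:
    feats = []
    for i, line in enumerate(lines):
        props = {"name": names[i]} if names is not None else {}
        feats.append({"type": "Feature", "geometry": mapping(line), "properties": props})
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_geojson_lines(path: str | Path) -> list[LineString]:
    fc = json.loads(Path(path).read_text())
    lines: list[LineString] = []
    for feat in fc["features"]:
        geom = shape(feat["geometry"])
        if isinstance(geom, MultiLineString):
            lines.extend(geom.geoms)
        elif isinstance(geom, LineString):
            lines.append(geom)
        else:
            raise ValueError(f"unexpected geometry type {geom.geom_type} in {path}")
    return lines


def write_geojson_points(points: dict[str, Point], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(pt),
            "properties": {"name": name},
        }
        for name, pt in points.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_geojson_points(path: str | Path) -> dict[str, Point]:
    fc = json.loads(Path(path).read_text())
    out: dict[str, Point] = {}
    for i, feat in enumerate(fc["features"]):
        geom = shape(feat["geometry"])
        if not isinstance(geom, Point):
            raise ValueError(f"expected Point geometry in {path}")
        out[str(feat.get("properties", {}).get("name", i))] = geom
    return out


def rasterize_lines(lines, template: RasterGrid) -> RasterGrid:
    """0/1 indicator raster of cells touched by any polyline.

    Lines are densified to half-cell spacing and the containing cell of each
    vertex marked; at that spacing a segment cannot skip over a cell it
    crosses by more than a corner clip.
    """
    out = np.zeros(template.shape)
    step = template.cell_size / 2.0
    for line in lines:
        n = max(int(np.ceil(line.length / step)) + 1, 2)
        pts = [line.interpolate(d) for d in np.linspace(0.0, line.length, n)]
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        inside = template.contains(xs, ys)
        row, col = template.xy_to_rowcol(xs[inside], ys[inside])
        out[row, col] = 1.0
    out[~template.valid] = np.nan
    return template.like(out)


def distance_grid(lines, template: RasterGrid) -> RasterGrid:
    """Euclidean distance (km) from each cell centre to the nearest line.

    Distances are exact point-to-segment distances against the union of the
    input polylines, not distances to rasterised line cells.
    """
    if not lines:
        raise ValueError("distance_grid requires at least one line feature")
    geom = unary_union(list(lines))
    xs, ys = template.cell_centers()
    from shapely import points as _mk_points, distance as _distance

    pts = _mk_points(np.column_stack([xs.ravel(), ys.ravel()]))
    d = _distance(pts, geom).reshape(template.shape)
    d = np.where(template.valid, d, np.nan)
    return template.like(d)
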