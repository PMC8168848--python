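"""Equal-area gridding of species ranges and per-cell score surfaces.

Species range polygons are overlaid on a square grid in an equal-area
metric CRS (default EPSG:3577, Australian Albers).  Per cell the module
computes richness (number of species present), the sum and the weighted
mean of a per-species score (sum of scores of species present divided by
the number present), and a square-root transform of the mean used to
damp the influence of a few extreme cells.  The mainland default is a
25 km cell; island groups are re-analysed on 1 km subgrids.

Coordinate systems: no reprojection is performed — range inputs must
already be in the grid's CRS.  Geographic (degree-based) CRS identifiers
are rejected.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from shapely import make_valid
from shapely.geometry import box, mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError

logger = logging.getLogger(__name__)

DEFAULT_CRS = "EPSG:3577"  # Australian Albers (equal-area, meters)
MAINLAND_CELL_SIZE = 25_000.0
ISLAND_CELL_SIZE = 1_000.0

# common geographic (degree-unit) codes we can recognize without a CRS library
_GEOGRAPHIC_CRS = {"EPSG:4326", "EPSG:4283", "EPSG:4269", "EPSG:4617", "EPSG:4167", "CRS84"}


class OccupancyRule(enum.Enum):
    """How a polygon claims a grid cell.

    ANY_INTERSECTION: the polygon overlaps the cell with positive area
    (conservative at range edges).  CENTROID: the cell's center point
    falls inside the polygon.
    """

    ANY_INTERSECTION = "any"
    CENTROID = "centroid"


class LayerKind(enum.Enum):
    RICHNESS = "richness"
    SUM = "sum"
    MEAN = "mean"
    SQRT_MEAN = "sqrt_mean"


@dataclass(frozen=True)
class GridSpec:
    """A row-major square grid; cell (i, j) covers the half-open square
    [x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)."""

    crs: str
    cell_size: float
    origin: tuple[float, float]
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_polygon(self, i: int, j: int):
        x0, y0 = self.origin
        s = self.cell_size
        return box(x0 + j * s, y0 + i * s, x0 + (j + 1) * s, y0 + (i + 1) * s)

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        x0, y0 = self.origin
        s = self.cell_size
        return (x0 + (j + 0.5) * s, y0 + (i + 0.5) * s)

    def cell_range_for_bounds(
        self, bounds: tuple[float, float, float, float]
    ) -> tuple[range, range]:
        """Row and column index ranges whose cells can touch `bounds`."""
        xmin, ymin, xmax, ymax = bounds
        x0, y0 = self.origin
        s = self.cell_size
        j0 = max(0, math.floor((xmin - x0) / s))
        j1 = min(self.n_cols - 1, math.floor((xmax - x0) / s))
        i0 = max(0, math.floor((ymin - y0) / s))
        i1 = min(self.n_rows - 1, math.floor((ymax - y0) / s))
        return range(i0, i1 + 1), range(j0, j1 + 1)


@dataclass(frozen=True)
class RangeMap:
    """A species' geographic range polygon in the grid CRS."""

    species_id: str
    geometry: BaseGeometry
    crs: str = DEFAULT_CRS

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise GeometryError(f"{self.species_id}: empty geometry")
        if not self.geometry.is_valid:
            repaired = make_valid(self.geometry)
            if repaired.is_empty or not repaired.is_valid:
                raise GeometryError(f"{self.species_id}: irreparable geometry")
            logger.warning("%s: invalid geometry repaired", self.species_id)
            object.__setattr__(self, "geometry", repaired)
        if self.geometry.area <= 0:
            raise GeometryError(f"{self.species_id}: zero-area geometry")

    @property
    def area_km2(self) -> float:
        return self.geometry.area / 1e6


@dataclass(frozen=True)
class ScoreRaster:
    """One per-cell layer on a grid; nodata cells hold NaN."""

    grid: GridSpec
    values: np.ndarray
    kind: LayerKind

    def __post_init__(self) -> None:
        if self.values.shape != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("layer shape does not match grid")
        if self.kind is LayerKind.RICHNESS:
            finite = self.values[np.isfinite(self.values)]
            if not np.allclose(finite, np.round(finite)) or (finite < 0).any():
                raise ValueError("richness layer must be non-negative integers")

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)


def _check_metric_crs(crs: str) -> str:
    c = str(crs).upper().replace(" ", "")
    if c in _GEOGRAPHIC_CRS:
        raise ValueError(
            f"{crs} is a geographic (degree-unit) CRS; the grid needs an "
            "equal-area metric CRS such as EPSG:3577"
        )
    return str(crs)


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float = MAINLAND_CELL_SIZE,
    crs: str = DEFAULT_CRS,
) -> GridSpec:
    """Cover `extent` (xmin, ymin, xmax, ymax) with a cell_size grid.

    The origin snaps down to an integer multiple of cell_size from the
    CRS origin, so grids built from different extents align; the cell
    count is a ceiling division, so the extent is always fully covered.
    """
    _check_metric_crs(crs)
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate extent")
    x0 = math.floor(xmin / cell_size) * cell_size
    y0 = math.floor(ymin / cell_size) * cell_size
    n_cols = math.ceil((xmax - x0) / cell_size)
    n_rows = math.ceil((ymax - y0) / cell_size)
    return GridSpec(crs=str(crs), cell_size=float(cell_size), origin=(x0, y0),
                    n_rows=n_rows, n_cols=n_cols)


def cells_occupied(
    range_map: RangeMap,
    grid: GridSpec,
    rule: OccupancyRule = OccupancyRule.ANY_INTERSECTION,
) -> set[tuple[int, int]]:
    """Cell indices (row, col) claimed by a range polygon.

    ANY_INTERSECTION requires the polygon-cell intersection to have
    positive area — touching a cell only along its boundary does not
    claim it.  CENTROID claims cells whose center lies in the polygon.
    """
    geom = range_map.geometry
    if geom.is_empty:
        raise GeometryError(f"{range_map.species_id}: empty geometry")
    rows, cols = grid.cell_range_for_bounds(geom.bounds)
    occupied: set[tuple[int, int]] = set()
    from shapely.geometry import Point

    for i in rows:
        for j in cols:
            if rule is OccupancyRule.CENTROID:
                if geom.contains(Point(*grid.cell_center(i, j))):
                    occupied.add((i, j))
            else:
                cell = grid.cell_polygon(i, j)
                if geom.intersects(cell) and geom.intersection(cell).area > 0.0:
                    occupied.add((i, j))
    return occupied


def _occupancy_by_species(
    ranges: Sequence[RangeMap], grid: GridSpec, rule: OccupancyRule
) -> dict[str, set[tuple[int, int]]]:
    seen: set[str] = set()
    occ: dict[str, set[tuple[int, int]]] = {}
    for r in ranges:
        if r.species_id in seen:
            raise ValueError(f"duplicate species_id {r.species_id!r}")
        seen.add(r.species_id)
        occ[r.species_id] = cells_occupied(r, grid, rule)
    return occ


def richness_map(
    ranges: Sequence[RangeMap],
    grid: GridSpec,
    rule: OccupancyRule = OccupancyRule.ANY_INTERSECTION,
) -> ScoreRaster:
    """Number of species occupying each cell (0 where none)."""
    layer = np.zeros((grid.n_rows, grid.n_cols), dtype=float)
    for cells in _occupancy_by_species(ranges, grid, rule).values():
        for i, j in cells:
            layer[i, j] += 1
    return ScoreRaster(grid=grid, values=layer, kind=LayerKind.RICHNESS)


def _sum_count(
    scores: Mapping[str, float],
    ranges: Sequence[RangeMap],
    grid: GridSpec,
    rule: OccupancyRule,
) -> tuple[np.ndarray, np.ndarray]:
    have = {r.species_id for r in ranges}
    missing = sorted(set(scores) - have)
    if missing:
        raise ValueError(f"scored species without a range: {', '.join(missing)}")
    scored_ranges = [r for r in ranges if r.species_id in scores]
    total = np.zeros((grid.n_rows, grid.n_cols), dtype=float)
    count = np.zeros((grid.n_rows, grid.n_cols), dtype=float)
    for sid, cells in _occupancy_by_species(scored_ranges, grid, rule).items():
        s = float(scores[sid])
        for i, j in cells:
            total[i, j] += s
            count[i, j] += 1
    return total, count


def sum_score_map(
    scores: Mapping[str, float],
    ranges: Sequence[RangeMap],
    grid: GridSpec,
    rule: OccupancyRule = OccupancyRule.ANY_INTERSECTION,
) -> ScoreRaster:
    """Per-cell sum of scores of species present (0 where none)."""
    total, _ = _sum_count(scores, ranges, grid, rule)
    return ScoreRaster(grid=grid, values=total, kind=LayerKind.SUM)


def mean_score_map(
    scores: Mapping[str, float],
    ranges: Sequence[RangeMap],
    grid: GridSpec,
    rule: OccupancyRule = OccupancyRule.ANY_INTERSECTION,
) -> ScoreRaster:
    """Weighted mean per cell: sum of scores of species present divided by
    the number present; NaN where no scored species occurs."""
    total, count = _sum_count(scores, ranges, grid, rule)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / count, np.nan)
    return ScoreRaster(grid=grid, values=mean, kind=LayerKind.MEAN)


def sqrt_transform(raster: ScoreRaster) -> ScoreRaster:
    """Element-wise square root, damping extreme cell values; nodata kept."""
    vals = raster.values
    finite = vals[np.isfinite(vals)]
    if (finite < 0).any():
        raise ValueError("negative cell value; square root undefined")
    return ScoreRaster(grid=raster.grid, values=np.sqrt(vals), kind=LayerKind.SQRT_MEAN)


def clip_ranges(
    ranges: Sequence[RangeMap], extent: tuple[float, float, float, float]
) -> list[RangeMap]:
    """Intersect ranges with a bounding box, dropping species left empty."""
    window = box(*extent)
    out = []
    for r in ranges:
        clipped = r.geometry.intersection(window)
        if not clipped.is_empty and clipped.area > 0:
            out.append(RangeMap(species_id=r.species_id, geometry=clipped, crs=r.crs))
    return out


def island_subgrid_analysis(
    ranges: Sequence[RangeMap],
    scores: Mapping[str, float],
    island_extents: Mapping[str, tuple[float, float, float, float]],
    cell_size: float = ISLAND_CELL_SIZE,
    crs: str = DEFAULT_CRS,
    rule: OccupancyRule = OccupancyRule.ANY_INTERSECTION,
) -> dict[str, dict[str, ScoreRaster]]:
    """Richness / mean / sqrt-mean products on fine subgrids of named
    island extents (default 1 km cells)."""
    if not island_extents:
        raise ValueError("no island extents given")
    out: dict[str, dict[str, ScoreRaster]] = {}
    for name, extent in island_extents.items():
        xmin, ymin, xmax, ymax = extent
        if not (xmax > xmin and ymax > ymin):
            raise ValueError(f"island {name!r}: degenerate extent")
        grid = build_grid(extent, cell_size=cell_size, crs=crs)
        local = clip_ranges(ranges, extent)
        local_scores = {k: v for k, v in scores.items()
                        if k in {r.species_id for r in local}}
        mean = mean_score_map(local_scores, local, grid, rule) if local_scores else \
            ScoreRaster(grid=grid,
                        values=np.full((grid.n_rows, grid.n_cols), np.nan),
                        kind=LayerKind.MEAN)
        out[name] = {
            "richness": richness_map(local, grid, rule),
            "mean": mean,
            "sqrt_mean": sqrt_transform(mean),
        }
    return out


# ---------------------------------------------------------------------------
# I/O: GeoJSON ranges in, text rasters out

def read_ranges_geojson(
    path: str | Path,
    species_key: str = "species_id",
    crs: str = DEFAULT_CRS,
) -> list[RangeMap]:
    """Load a GeoJSON FeatureCollection of range polygons.

    Coordinates are taken verbatim — they must already be in the grid's
    equal-area metric CRS (`crs` records which one that is).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError("expected a GeoJSON FeatureCollection")
    ranges = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if species_key not in props:
            raise GeometryError(f"feature missing property {species_key!r}")
        ranges.append(
            RangeMap(species_id=str(props[species_key]),
                     geometry=shape(feat["geometry"]), crs=crs)
        )
    return ranges


def write_ranges_geojson(ranges: Sequence[RangeMap], path: str | Path,
                         species_key: str = "species_id") -> None:
    doc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {species_key: r.species_id,
                               "area_km2": round(r.area_km2, 3)},
                "geometry": mapping(r.geometry),
            }
            for r in ranges
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def raster_to_frame(raster: ScoreRaster):
    """Long-format table: row, col, cell center x/y, layer kind, value."""
    import pandas as pd

    rows = []
    for i in range(raster.grid.n_rows):
        for j in range(raster.grid.n_cols):
            x, y = raster.grid.cell_center(i, j)
            v = raster.values[i, j]
            rows.append({"row": i, "col": j, "cell_x": x, "cell_y": y,
                         "layer": raster.kind.value,
                         "value": float(v) if np.isfinite(v) else None})
    return pd.DataFrame(rows, columns=["row", "col", "cell_x", "cell_y", "layer", "value"])


def write_raster_ascii(raster: ScoreRaster, path: str | Path,
                       nodata: float = -9999.0) -> None:
    """ESRI ASCII grid export (plain-text raster; row 0 is the top row)."""
    g = raster.grid
    vals = np.where(np.isfinite(raster.values), raster.values, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.origin[0]}\n")
        fh.write(f"yllcorner {g.origin[1]}\n")
        fh.write(f"cellsize {g.cell_size}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for i in range(g.n_rows - 1, -1, -1):  # ASCII grids list top row first
            fh.write(" ".join(f"{v:.6g}" for v in vals[i]) + "\n")
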