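"""Regular-grid raster model and overlay algebra.

Every stage of the fire-exposure pipeline works on rasters that share one
declared grid: same origin, resolution and shape.  The algebra here is
deliberately small — normalise a mask into a weight layer, multiply layers
cellwise, sum cells, resample between grids, rasterize polygons — because the
exposure statistics are compositions of exactly these operations.

Conventions: cells are 0-based row-major; row 0 is the northern edge; each
cell covers a half-open box so a point on a shared edge belongs to exactly
one cell.  Cell area (km²) is an explicit property of the grid rather than
being derived from latitude; pass ``latitude_corrected_cell_areas`` where a
per-cell correction is wanted.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from shapely.geometry import box as _shapely_box, mapping as _shapely_mapping, shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "GridSpec",
    "GridRaster",
    "AlignmentError",
    "InvalidGeometryError",
    "EmptyRegionError",
    "RasterKind",
    "make_grid",
    "rasterize_polygons",
    "normalize_mask",
    "overlay_product",
    "raster_sum",
    "resample_to",
    "latitude_corrected_cell_areas",
    "read_polygons_geojson",
    "write_polygons_geojson",
    "read_raster",
    "write_raster",
    "write_ascii_grid",
    "read_ascii_grid",
]

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEGREE = EARTH_RADIUS_KM * math.pi / 180.0  # ≈ 111.195

DEFAULT_NODATA = -9999.0

RasterKind = Literal["occurrence", "intensity", "weight", "density", "mask", "generic"]


class AlignmentError(ValueError):
    """Two rasters do not share origin, resolution and shape exactly."""


class InvalidGeometryError(ValueError):
    """Degenerate bounds or invalid polygon input."""


class EmptyRegionError(ValueError):
    """An operation that needs at least one positive cell got none."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat grid.

    ``origin_lon``/``origin_lat`` locate the *north-west* corner of cell
    (0, 0); ``resolution`` is the cell edge in degrees; ``cell_area`` is the
    nominal constant area of one cell in km².
    """

    origin_lon: float
    origin_lat: float
    n_rows: int
    n_cols: int
    resolution: float
    cell_area: float = 1.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidGeometryError("grid must have at least one row and column")
        if self.resolution <= 0:
            raise InvalidGeometryError("resolution must be positive")
        if self.cell_area <= 0:
            raise InvalidGeometryError("cell_area must be positive")

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of the full grid footprint."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.resolution,
            self.origin_lon + self.n_cols * self.resolution,
            self.origin_lat,
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Cell (row, col) containing a point, or None when outside.

        Half-open boxes: a point on the western/northern edge of a cell
        belongs to it; the eastern/southern edge belongs to the neighbour.
        """
        c = math.floor((lon - self.origin_lon) / self.resolution)
        r = math.floor((self.origin_lat - lat) / self.resolution)
        if lat == self.origin_lat:
            r = 0  # the very top edge is inside row 0
        if 0 <= r < self.n_rows and 0 <= c < self.n_cols:
            return (r, c)
        return None

    def cells_of(self, lons: np.ndarray, lats: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised cell lookup; returns (rows, cols, inside-mask)."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        cols = np.floor((lons - self.origin_lon) / self.resolution).astype(int)
        rows = np.floor((self.origin_lat - lats) / self.resolution).astype(int)
        rows[lats == self.origin_lat] = 0
        inside = (rows >= 0) & (rows < self.n_rows) & (cols >= 0) & (cols < self.n_cols)
        return rows, cols, inside

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lons, lats) of cell centres, each 1-D along its axis."""
        lons = self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.resolution
        lats = self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.resolution
        return lons, lats

    def lon_edges(self) -> np.ndarray:
        return self.origin_lon + np.arange(self.n_cols + 1) * self.resolution

    def lat_edges(self) -> np.ndarray:
        """Latitude edges from north to south (decreasing)."""
        return self.origin_lat - np.arange(self.n_rows + 1) * self.resolution

    def compatible_with(self, other: "GridSpec") -> bool:
        return (
            math.isclose(self.origin_lon, other.origin_lon, abs_tol=1e-12)
            and math.isclose(self.origin_lat, other.origin_lat, abs_tol=1e-12)
            and self.shape == other.shape
            and math.isclose(self.resolution, other.resolution, rel_tol=1e-12)
        )


_KIND_CHECKS = {
    "occurrence": lambda v: np.isin(v, (0.0, 1.0)).all(),
    "mask": lambda v: np.isin(v, (0.0, 1.0)).all(),
    "weight": lambda v: (v >= 0).all() and abs(float(v.sum()) - 1.0) <= 1e-9,
    "density": lambda v: (v >= 0).all(),
    "intensity": lambda v: ((v == 0) | (v >= 300.0)).all(),
    "generic": lambda v: True,
}


@dataclass
class GridRaster:
    """Per-cell values on a :class:`GridSpec`.

    ``kind`` declares the semantics and its invariant (checked on request):
    occurrence/mask in {0,1}; weight non-negative summing to 1; density
    non-negative; intensity either 0 (no fire) or a brightness ≥ 300 K.
    """

    spec: GridSpec
    values: np.ndarray
    kind: RasterKind = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise AlignmentError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )

    def validate(self) -> "GridRaster":
        check = _KIND_CHECKS.get(self.kind)
        if check is None:
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if not check(self.values):
            raise ValueError(f"values violate the {self.kind!r} invariant")
        return self

    def copy(self, *, kind: RasterKind | None = None) -> "GridRaster":
        return GridRaster(self.spec, self.values.copy(), kind or self.kind)


# ---------------------------------------------------------------------------
# grid construction & rasterization
# ---------------------------------------------------------------------------

def make_grid(
    bounds: tuple[float, float, float, float],
    resolution: float,
    cell_area: float = 1.0,
) -> GridSpec:
    """Smallest grid whose footprint covers ``bounds``.

    ``bounds`` is (lon_min, lat_min, lon_max, lat_max).  The number of rows
    and columns is the ceiling of extent/resolution, so the grid may overhang
    the box on the south and east.
    """
    lon_min, lat_min, lon_max, lat_max = bounds
    if not (lon_max > lon_min and lat_max > lat_min):
        raise InvalidGeometryError(f"degenerate bounds {bounds}")
    if resolution <= 0:
        raise InvalidGeometryError("resolution must be positive")
    # guard against float fuzz turning an exact division into ceil(n+eps)=n+1
    n_cols = math.ceil(round((lon_max - lon_min) / resolution, 9))
    n_rows = math.ceil(round((lat_max - lat_min) / resolution, 9))
    return GridSpec(lon_min, lat_max, n_rows, n_cols, resolution, cell_area)


def _as_geometries(polygons) -> list[BaseGeometry]:
    if isinstance(polygons, BaseGeometry):
        return [polygons]
    return list(polygons)


def rasterize_polygons(
    polygons,
    spec: GridSpec,
    rule: Literal["cell-centre-in", "any-overlap"] = "cell-centre-in",
) -> GridRaster:
    """Binary mask of the cells a polygon set claims under ``rule``.

    ``cell-centre-in`` (default) marks a cell whose centre lies in a polygon;
    ``any-overlap`` marks a cell whose box intersects a polygon.
    """
    geoms = _as_geometries(polygons)
    mask = np.zeros(spec.shape)
    if not geoms:
        warnings.warn("empty polygon set: rasterization yields an all-zero mask")
        return GridRaster(spec, mask, "mask")
    union = shapely.union_all(geoms)
    if not union.is_valid:
        raise InvalidGeometryError("invalid polygon input")
    if rule == "cell-centre-in":
        lons, lats = spec.cell_centers()
        glon, glat = np.meshgrid(lons, lats)
        inside = shapely.contains_xy(union, glon.ravel(), glat.ravel())
        mask = inside.reshape(spec.shape).astype(float)
    elif rule == "any-overlap":
        lon_e = spec.lon_edges()
        lat_e = spec.lat_edges()
        shapely.prepare(union)
        for r in range(spec.n_rows):
            for c in range(spec.n_cols):
                cell = _shapely_box(lon_e[c], lat_e[r + 1], lon_e[c + 1], lat_e[r])
                if shapely.intersects(union, cell):
                    mask[r, c] = 1.0
    else:
        raise ValueError(f"unknown rasterization rule {rule!r}")
    return GridRaster(spec, mask, "mask")


# ---------------------------------------------------------------------------
# overlay algebra
# ---------------------------------------------------------------------------

def normalize_mask(mask: GridRaster) -> GridRaster:
    """Rescale a non-negative raster so its cells sum to one (a weight layer)."""
    total = math.fsum(mask.values.ravel())
    if total <= 0:
        raise EmptyRegionError("cannot normalize a mask with no positive cells")
    return GridRaster(mask.spec, mask.values / total, "weight")


def overlay_product(a: GridRaster, b: GridRaster) -> GridRaster:
    """Cellwise product of two alignment-compatible rasters."""
    if not a.spec.compatible_with(b.spec):
        raise AlignmentError("rasters are not on the same grid; resample explicitly first")
    return GridRaster(a.spec, a.values * b.values, "generic")


def raster_sum(r: GridRaster) -> float:
    """Compensated sum of every cell value."""
    return math.fsum(r.values.ravel())


def _axis_overlap(src_edges: np.ndarray, dst_edges: np.ndarray, descending: bool) -> np.ndarray:
    """Overlap lengths between source and target intervals along one axis.

    Returns a (n_dst, n_src) matrix of interval-overlap lengths.
    """
    if descending:
        src_lo, src_hi = src_edges[1:], src_edges[:-1]
        dst_lo, dst_hi = dst_edges[1:], dst_edges[:-1]
    else:
        src_lo, src_hi = src_edges[:-1], src_edges[1:]
        dst_lo, dst_hi = dst_edges[:-1], dst_edges[1:]
    lo = np.maximum(dst_lo[:, None], src_lo[None, :])
    hi = np.minimum(dst_hi[:, None], src_hi[None, :])
    return np.clip(hi - lo, 0.0, None)


def resample_to(
    r: GridRaster,
    spec: GridSpec,
    method: Literal["nearest", "area-weighted-mean"] = "nearest",
) -> GridRaster:
    """Re-express a raster on another grid.

    ``nearest`` assigns each target cell the value of the source cell holding
    its centre (categorical layers: occurrence, mask).  ``area-weighted-mean``
    averages source values weighted by geometric overlap (continuous layers:
    density, intensity); the per-cell *mean* is preserved, while totals scale
    with the target grid's declared cell area.
    """
    if r.spec.compatible_with(spec):
        return GridRaster(spec, r.values.copy(), r.kind)
    if method == "nearest":
        lons, lats = spec.cell_centers()
        glon, glat = np.meshgrid(lons, lats)
        rows, cols, inside = r.spec.cells_of(glon.ravel(), glat.ravel())
        out = np.zeros(spec.n_cells)
        rows = np.clip(rows, 0, r.spec.n_rows - 1)
        cols = np.clip(cols, 0, r.spec.n_cols - 1)
        vals = r.values[rows, cols]
        out[inside] = vals[inside]
        return GridRaster(spec, out.reshape(spec.shape), r.kind)
    if method == "area-weighted-mean":
        w_rows = _axis_overlap(r.spec.lat_edges(), spec.lat_edges(), descending=True)
        w_cols = _axis_overlap(r.spec.lon_edges(), spec.lon_edges(), descending=False)
        weight_tot = (w_rows.sum(axis=1)[:, None]) * (w_cols.sum(axis=1)[None, :])
        num = w_rows @ r.values @ w_cols.T
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(weight_tot > 0, num / weight_tot, 0.0)
        return GridRaster(spec, out, r.kind if r.kind in ("density", "intensity") else "generic")
    raise ValueError(f"unknown resampling method {method!r}")


def latitude_corrected_cell_areas(spec: GridSpec) -> np.ndarray:
    """Per-cell spherical areas (km²) for a lon/lat grid.

    Exact on the sphere: res·(sin φ_n − sin φ_s)·R²·π/180 per cell.
    An optional alternative to the constant ``cell_area`` convention.
    """
    lat_e = np.deg2rad(spec.lat_edges())
    band = np.sin(lat_e[:-1]) - np.sin(lat_e[1:])  # north minus south, positive
    areas_row = EARTH_RADIUS_KM**2 * np.deg2rad(spec.resolution) * band
    return np.repeat(areas_row[:, None], spec.n_cols, axis=1)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_polygons_geojson(path: str | Path) -> list[BaseGeometry]:
    """Polygon/MultiPolygon geometries from a GeoJSON file (any root type)."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") == "FeatureCollection":
        return [_shapely_shape(f["geometry"]) for f in doc["features"]]
    if doc.get("type") == "Feature":
        return [_shapely_shape(doc["geometry"])]
    return [_shapely_shape(doc)]


def write_polygons_geojson(path: str | Path, geoms: Iterable[BaseGeometry], properties: Sequence[dict] | None = None) -> None:
    geoms = list(geoms)
    props = list(properties) if properties is not None else [{} for _ in geoms]
    doc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": _shapely_mapping(g), "properties": p}
            for g, p in zip(geoms, props)
        ],
    }
    Path(path).write_text(json.dumps(doc))


def write_raster(path: str | Path, r: GridRaster, nodata: float = DEFAULT_NODATA) -> None:
    """Single-band TIFF plus a ``.json`` sidecar describing the grid."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, r.values.astype(np.float64))
    sidecar = {
        "origin_lon": r.spec.origin_lon,
        "origin_lat": r.spec.origin_lat,
        "n_rows": r.spec.n_rows,
        "n_cols": r.spec.n_cols,
        "resolution": r.spec.resolution,
        "cell_area": r.spec.cell_area,
        "kind": r.kind,
        "nodata": nodata,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_raster(path: str | Path) -> GridRaster:
    import tifffile

    path = Path(path)
    values = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    spec = GridSpec(
        meta["origin_lon"], meta["origin_lat"], meta["n_rows"], meta["n_cols"],
        meta["resolution"], meta["cell_area"],
    )
    values = np.where(values == meta.get("nodata", DEFAULT_NODATA), 0.0, values)
    return GridRaster(spec, values, meta.get("kind", "generic"))


def write_ascii_grid(path: str | Path, r: GridRaster, nodata: float = DEFAULT_NODATA) -> None:
    """Arc/Info ASCII grid export (plain text, fixture friendly)."""
    lon_min, lat_min, _, _ = r.spec.bounds
    header = (
        f"ncols {r.spec.n_cols}\n"
        f"nrows {r.spec.n_rows}\n"
        f"xllcorner {lon_min!r}\n"
        f"yllcorner {lat_min!r}\n"
        f"cellsize {r.spec.resolution!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in r.values)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, cell_area: float = 1.0, kind: RasterKind = "generic") -> GridRaster:
    lines = Path(path).read_text().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
    ):
        key, val = lines[i].split()
        hdr[key.lower()] = float(val)
        i += 1
    values = np.loadtxt(lines[i:], ndmin=2)
    n_rows, n_cols = int(hdr["nrows"]), int(hdr["ncols"])
    res = hdr["cellsize"]
    spec = GridSpec(hdr["xllcorner"], hdr["yllcorner"] + n_rows * res, n_rows, n_cols, res, cell_area)
    values = np.where(values == hdr.get("nodata_value", DEFAULT_NODATA), 0.0, values)
    return GridRaster(spec, values, kind)
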