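"""Core spatial data types and file I/O.

Conventions used throughout the package:

* All coordinates are planar, projected, in metres; distances are Euclidean.
  The package never computes on geographic (lon/lat) coordinates.
* :class:`Raster` origin is the lower-left corner of the lower-left cell;
  row 0 of ``values`` is the **southernmost** row; a cell value represents
  the cell centre.  This matches the ESRI ASCII grid convention (which
  stores rows north-to-south; the reader/writer flips accordingly).
* Missing cells are ``NaN`` in memory; the ``nodata`` sentinel only
  appears on disk.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely import contains_xy

__all__ = [
    "LandUse",
    "SampleSite",
    "Raster",
    "LanduseMap",
    "SchemaError",
    "FormatError",
    "read_sample_table",
    "write_sample_table",
    "read_raster",
    "write_raster",
    "read_landuse_geojson",
    "rasterize_landuse",
    "compute_slope",
    "fill_nodata_edges",
]


class SchemaError(ValueError):
    """Tabular input does not match the declared schema."""


class FormatError(ValueError):
    """Raster/vector file is malformed."""


class LandUse(str, Enum):
    """Land-use stratum of a survey site or map cell."""

    FOREST = "forest"
    GRASSLAND = "grassland"
    AGRICULTURE = "agriculture"

    @property
    def code(self) -> int:
        return {"forest": 1, "grassland": 2, "agriculture": 3}[self.value]

    @classmethod
    def from_code(cls, code: int) -> "LandUse":
        return {1: cls.FOREST, 2: cls.GRASSLAND, 3: cls.AGRICULTURE}[int(code)]


@dataclass(frozen=True)
class SampleSite:
    """One soil survey point.

    ``soc_a`` is the organic-carbon concentration of the mineral A horizon
    (g C kg^-1 dry soil); ``soc_o``/``o_thickness`` describe the organic
    surface layer where present; ``bulk_density`` (g cm^-3) and
    ``coarse_pct`` (volume % of the >2 mm fraction) convert concentration
    to an areal stock.
    """

    site_id: str
    x: float
    y: float
    altitude: float
    land_use: LandUse
    soc_a: float
    bulk_density: float
    coarse_pct: float
    soc_o: float | None = None
    o_thickness: float = 0.0
    slope: float | None = None
    ndvi: float | None = None

    def __post_init__(self) -> None:
        if not self.soc_a > 0:
            raise ValueError(f"site {self.site_id}: soc_a must be > 0, got {self.soc_a}")
        if self.o_thickness < 0:
            raise ValueError(f"site {self.site_id}: o_thickness must be >= 0")
        if not 0.0 <= self.coarse_pct <= 100.0:
            raise ValueError(
                f"site {self.site_id}: coarse_pct must be in [0, 100], got {self.coarse_pct}"
            )
        if not self.bulk_density > 0:
            raise ValueError(f"site {self.site_id}: bulk_density must be > 0")
        has_o = self.o_thickness > 0
        if has_o != (self.soc_o is not None):
            raise ValueError(
                f"site {self.site_id}: soc_o must be present iff o_thickness > 0"
            )
        if self.ndvi is not None and not -1.0 <= self.ndvi <= 1.0:
            raise ValueError(f"site {self.site_id}: ndvi outside [-1, 1]")


def site_coords(sites: Sequence[SampleSite]) -> np.ndarray:
    """(n, 2) array of x, y coordinates."""
    return np.array([[s.x, s.y] for s in sites], dtype=float)


def site_values(sites: Sequence[SampleSite], selector) -> np.ndarray:
    """Extract a numeric attribute from each site.

    ``selector`` is an attribute name or a callable ``site -> float``.
    """
    if callable(selector):
        return np.array([float(selector(s)) for s in sites])
    return np.array([float(getattr(s, selector)) for s in sites])


@dataclass
class Raster:
    """Georeferenced regular grid with square cells.

    Row 0 is the southernmost row; ``(x_origin, y_origin)`` is the outer
    corner of cell ``[0, 0]``.  ``values`` holds floats with NaN for
    missing cells; ``nodata`` is the on-disk sentinel.
    """

    values: np.ndarray
    x_origin: float
    y_origin: float
    cell_size: float
    nodata: float = -9999.0
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-centre coordinates, shape = values.shape."""
        xs = self.x_origin + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y)."""
        col = np.floor((np.asarray(x) - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.y_origin) / self.cell_size).astype(int)
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell lookup; NaN outside the grid."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.index_of(x, y)
        out = np.full(x.shape, np.nan)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def same_grid(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    def copy_with(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class LanduseMap:
    """Land-use classes as planar polygons (projected CRS, metres)."""

    polygons: list[tuple[LandUse, BaseGeometry]]
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if not self.polygons:
            raise ValueError("LanduseMap needs at least one polygon")
        for lu, geom in self.polygons:
            if geom.area <= 0:
                raise ValueError(f"polygon for {lu.value} has non-positive area")

    def area_ha(self) -> dict[LandUse, float]:
        """Mapped area per class in hectares (1 ha = 10^4 m^2)."""
        out: dict[LandUse, float] = {}
        for lu, geom in self.polygons:
            out[lu] = out.get(lu, 0.0) + geom.area / 1e4
        return out


# ---------------------------------------------------------------------------
# sample table I/O

_MANDATORY = [
    "site_id", "x", "y", "altitude", "land_use",
    "soc_a", "soc_o", "o_thickness", "bulk_density", "coarse_pct",
]
_OPTIONAL = ["slope", "ndvi"]


def read_sample_table(path, crs_id: str = "local-metric") -> list[SampleSite]:
    """Read a survey CSV into :class:`SampleSite` records.

    Missing ``soc_o``/``o_thickness`` entries mean "no O horizon".  Rows
    violating a site invariant are rejected with a row-numbered error.
    """
    df = pd.read_csv(path, dtype={"site_id": str, "land_use": str})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    sites: list[SampleSite] = []
    numeric = ["x", "y", "altitude", "soc_a", "soc_o", "o_thickness",
               "bulk_density", "coarse_pct"] + [c for c in _OPTIONAL if c in df.columns]
    for i, rec in enumerate(df.to_dict("records")):
        rownum = i + 2  # 1-based with header line
        vals = {}
        for c in numeric:
            raw = rec.get(c)
            if raw is None or (isinstance(raw, float) and math.isnan(raw)) or raw == "":
                vals[c] = None
                continue
            try:
                vals[c] = float(raw)
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"row {rownum}: non-numeric value {raw!r} in column {c!r}") from exc
        try:
            lu = LandUse(str(rec["land_use"]).strip().lower())
        except ValueError as exc:
            raise SchemaError(f"row {rownum}: unknown land_use {rec['land_use']!r}") from exc
        try:
            sites.append(SampleSite(
                site_id=str(rec["site_id"]),
                x=vals["x"], y=vals["y"], altitude=vals["altitude"], land_use=lu,
                soc_a=vals["soc_a"],
                bulk_density=vals["bulk_density"], coarse_pct=vals["coarse_pct"],
                soc_o=vals["soc_o"],
                o_thickness=vals["o_thickness"] if vals["o_thickness"] is not None else 0.0,
                slope=vals.get("slope"), ndvi=vals.get("ndvi"),
            ))
        except ValueError as exc:
            raise SchemaError(f"row {rownum}: {exc}") from exc
    return sites


def write_sample_table(sites: Iterable[SampleSite], path) -> None:
    rows = []
    for s in sites:
        rows.append({
            "site_id": s.site_id, "x": s.x, "y": s.y, "altitude": s.altitude,
            "land_use": s.land_use.value, "soc_a": s.soc_a,
            "soc_o": s.soc_o if s.soc_o is not None else "",
            "o_thickness": s.o_thickness, "bulk_density": s.bulk_density,
            "coarse_pct": s.coarse_pct,
            "slope": s.slope if s.slope is not None else "",
            "ndvi": s.ndvi if s.ndvi is not None else "",
        })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# raster I/O: ESRI ASCII grid and GeoTIFF

def read_raster(path) -> Raster:
    """Read an ESRI ASCII grid (``.asc``) or GeoTIFF (``.tif``/``.tiff``)."""
    p = Path(path)
    if p.suffix.lower() == ".asc":
        return _read_asc(p)
    if p.suffix.lower() in (".tif", ".tiff"):
        return _read_geotiff(p)
    raise FormatError(f"unsupported raster extension: {p.suffix}")


def write_raster(r: Raster, path) -> None:
    p = Path(path)
    if p.suffix.lower() == ".asc":
        _write_asc(r, p)
    elif p.suffix.lower() in (".tif", ".tiff"):
        _write_geotiff(r, p)
    else:
        raise FormatError(f"unsupported raster extension: {p.suffix}")


def _read_asc(path: Path) -> Raster:
    header: dict[str, float] = {}
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in keys:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise FormatError(f"{path}: missing header keyword {req}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", -9999.0)
    try:
        data = np.array([float(v) for line in lines[i:] for v in line.split()])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric grid value") from exc
    if data.size != nrows * ncols:
        raise FormatError(
            f"{path}: header declares {nrows}x{ncols}={nrows * ncols} cells, found {data.size}"
        )
    grid = data.reshape(nrows, ncols)[::-1].copy()  # file is north-first; row 0 = south
    grid[grid == nodata] = np.nan
    return Raster(grid, header["xllcorner"], header["yllcorner"], header["cellsize"],
                  nodata=nodata)


def _write_asc(r: Raster, path: Path) -> None:
    grid = r.values[::-1]  # write north-first
    with open(path, "w") as fh:
        fh.write(f"ncols {r.n_cols}\n")
        fh.write(f"nrows {r.n_rows}\n")
        fh.write(f"xllcorner {r.x_origin!r}\n")
        fh.write(f"yllcorner {r.y_origin!r}\n")
        fh.write(f"cellsize {r.cell_size!r}\n")
        fh.write(f"NODATA_value {r.nodata!r}\n")
        out = np.where(np.isnan(grid), r.nodata, grid)
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


# GeoTIFF tag ids
_TAG_PIXEL_SCALE = 33550   # ModelPixelScaleTag
_TAG_TIEPOINT = 33922      # ModelTiepointTag
_TAG_GDAL_NODATA = 42113


def _write_geotiff(r: Raster, path: Path) -> None:
    import tifffile

    y_top = r.y_origin + r.n_rows * r.cell_size
    data = np.where(np.isnan(r.values[::-1]), r.nodata, r.values[::-1]).astype(np.float64)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (r.cell_size, r.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, r.x_origin, y_top, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(r.nodata)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def _read_geotiff(path: Path) -> Raster:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        if data.ndim != 2:
            raise FormatError(f"{path}: expected single-band raster")
        tags = {t.code: t.value for t in page.tags.values()}
    if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
        raise FormatError(f"{path}: missing georeferencing tags")
    sx, sy = tags[_TAG_PIXEL_SCALE][0], tags[_TAG_PIXEL_SCALE][1]
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise FormatError(f"{path}: non-square cells unsupported")
    x0 = tags[_TAG_TIEPOINT][3]
    y_top = tags[_TAG_TIEPOINT][4]
    nodata = float(tags.get(_TAG_GDAL_NODATA, -9999.0))
    grid = data[::-1].copy()
    grid[grid == nodata] = np.nan
    y0 = y_top - data.shape[0] * sy
    return Raster(grid, x0, y0, float(sx), nodata=nodata)


# ---------------------------------------------------------------------------
# vector I/O and rasterization

def read_landuse_geojson(path, crs_id: str = "local-metric") -> LanduseMap:
    """Read a GeoJSON FeatureCollection with a ``land_use`` property."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    polys = []
    for feat in gj.get("features", []):
        lu = LandUse(feat["properties"]["land_use"])
        polys.append((lu, shapely_shape(feat["geometry"])))
    return LanduseMap(polys, crs_id=crs_id)


def write_landuse_geojson(m: LanduseMap, path) -> None:
    from shapely.geometry import mapping

    feats = [
        {"type": "Feature", "properties": {"land_use": lu.value}, "geometry": mapping(geom)}
        for lu, geom in m.polygons
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def rasterize_landuse(m: LanduseMap, template: Raster) -> Raster:
    """Label template cells by the class polygon containing the cell centre.

    Cell centres on a shared boundary go to the first-listed polygon
    (deterministic tie-break); uncovered cells stay nodata.
    """
    X, Y = template.cell_centers()
    out = np.full(template.values.shape, np.nan)
    unassigned = np.ones(template.values.shape, dtype=bool)
    for lu, geom in m.polygons:
        # covers = contains boundary points too, so edge centres resolve
        hit = unassigned & _covers_xy(geom, X, Y)
        out[hit] = lu.code
        unassigned &= ~hit
    if np.all(np.isnan(out)):
        raise FormatError("polygons do not overlap the template raster extent")
    return template.copy_with(out)


def _covers_xy(geom: BaseGeometry, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    from shapely import covers, points

    pts = points(np.column_stack([X.ravel(), Y.ravel()]))
    return covers(geom, pts).reshape(X.shape)


# ---------------------------------------------------------------------------
# terrain

def fill_nodata_edges(r: Raster) -> Raster:
    """Replace nodata border rows/columns with the nearest interior values.

    Convenience for derived rasters (e.g. slope) whose border is undefined
    but which must cover every site when sampled as a covariate.
    """
    v = r.values.copy()
    if v.shape[0] >= 3:
        v[0, :] = np.where(np.isnan(v[0, :]), v[1, :], v[0, :])
        v[-1, :] = np.where(np.isnan(v[-1, :]), v[-2, :], v[-1, :])
    if v.shape[1] >= 3:
        v[:, 0] = np.where(np.isnan(v[:, 0]), v[:, 1], v[:, 0])
        v[:, -1] = np.where(np.isnan(v[:, -1]), v[:, -2], v[:, -1])
    return r.copy_with(v)


def compute_slope(dem: Raster) -> Raster:
    """Terrain slope in degrees via Horn's 3x3 finite-difference stencil.

    Border cells are nodata.  The DEM interior must be hole-free.
    """
    if dem.n_rows < 3 or dem.n_cols < 3:
        raise ValueError("DEM must be at least 3x3 for slope computation")
    z = dem.values
    if np.isnan(z[1:-1, 1:-1]).any():
        warnings.warn("DEM has interior nodata holes; slope will be NaN there")
    d = dem.cell_size
    # Horn 1981 weights; with row 0 = south, "north" neighbours are row+1.
    sw, s_, se = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    w_, e_ = z[1:-1, :-2], z[1:-1, 2:]
    nw, n_, ne = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * d)
    dzdy = ((ne + 2 * n_ + nw) - (se + 2 * s_ + sw)) / (8 * d)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    out = np.full(z.shape, np.nan)
    out[1:-1, 1:-1] = slope
    return dem.copy_with(out)
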