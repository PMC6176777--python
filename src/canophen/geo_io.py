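"""Raster and vector I/O for the phenotyping pipeline.

Rasters are exchanged as GeoTIFF (written through :mod:`tifffile` with the
standard GeoTIFF georeferencing tags), plot boundaries as GeoJSON, and all
tables as plain CSV.  Reflectance follows the multispectral-camera encoding in
which a 16-bit digital number of 32768 corresponds to 100 % reflectance.

Conventions
-----------
* World coordinates are metres in a local frame; raster row 0 is the north
  edge and column 0 the west edge (y decreases with row index).
* All raster indexing is 0-based.
* A pixel belongs to a polygon iff its *center* is inside it; centers exactly
  on the boundary follow a half-open rule (west/north edges inclusive) so
  that adjacent plots partition the grid without sharing pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon, mapping, shape

__all__ = [
    "DN_FULL_SCALE",
    "BAND_NAMES",
    "BandDefinition",
    "REDEDGE_BANDS",
    "GridGeometry",
    "BandStack",
    "PlotRecord",
    "PlotSet",
    "FormatError",
    "ValidationError",
    "scale_dn_to_reflectance",
    "read_multiband_raster",
    "write_multiband_raster",
    "read_singleband_raster",
    "write_singleband_raster",
    "read_plot_polygons",
    "write_plot_polygons",
    "rasterize_plot",
]

#: Digital number equal to 100 % reflectance in 16-bit multispectral products.
DN_FULL_SCALE = 32768

#: Canonical band order of the 5-band stack.
BAND_NAMES = ("blue", "green", "red", "red_edge", "nir")

# GeoTIFF / GDAL tag codes.
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class FormatError(ValueError):
    """Raised when a file does not match the expected raster/vector format."""


class ValidationError(ValueError):
    """Raised when vector data violates the PlotSet contract."""


@dataclass(frozen=True)
class BandDefinition:
    """Spectral band described by its center wavelength and FWHM bandwidth."""

    name: str
    center_nm: float
    fwhm_nm: float

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError(f"band {self.name!r}: fwhm_nm must be > 0")


#: The five bands of the RedEdge-class multispectral camera.
REDEDGE_BANDS = (
    BandDefinition("blue", 475.0, 20.0),
    BandDefinition("green", 560.0, 20.0),
    BandDefinition("red", 668.0, 10.0),
    BandDefinition("red_edge", 717.0, 10.0),
    BandDefinition("nir", 840.0, 40.0),
)


@dataclass(frozen=True)
class GridGeometry:
    """Affine geometry of a north-up raster grid.

    Parameters
    ----------
    x0, y0
        World coordinates of the *outer corner* of the top-left pixel
        (west edge, north edge).
    px, py
        Pixel size in metres along x and y (both positive; rows advance
        southwards, i.e. decreasing y).
    n_rows, n_cols
        Raster shape.
    """

    x0: float
    y0: float
    px: float
    py: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.px <= 0 or self.py <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def col_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.n_cols) + 0.5) * self.px

    def row_centers(self) -> np.ndarray:
        return self.y0 - (np.arange(self.n_rows) + 0.5) * self.py

    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the raster extent."""
        return (
            self.x0,
            self.y0 - self.n_rows * self.py,
            self.x0 + self.n_cols * self.px,
            self.y0,
        )

    def contains_polygon(self, poly: Polygon) -> bool:
        minx, miny, maxx, maxy = self.bounds()
        bminx, bminy, bmaxx, bmaxy = poly.bounds
        return bminx >= minx and bminy >= miny and bmaxx <= maxx and bmaxy <= maxy


@dataclass
class BandStack:
    """Co-registered reflectance rasters for the five spectral bands.

    ``data`` has shape ``(5, n_rows, n_cols)`` in reflectance units (1.0 =
    100 %); nodata pixels are NaN in memory.
    """

    data: np.ndarray
    grid: GridGeometry
    band_names: tuple[str, ...] = BAND_NAMES

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.band_names):
            raise ValueError(
                f"expected ({len(self.band_names)}, rows, cols) array, "
                f"got {self.data.shape}"
            )
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("band array shape does not match grid geometry")
        valid = self.data[np.isfinite(self.data)]
        if valid.size and valid.min() < 0:
            raise ValueError("reflectance must be >= 0 where not nodata")

    def band(self, name: str) -> np.ndarray:
        try:
            return self.data[self.band_names.index(name)]
        except ValueError:
            raise KeyError(f"no band named {name!r}") from None


@dataclass(frozen=True)
class PlotRecord:
    plot_id: str
    polygon: Polygon
    line: str | None = None
    treatment: str | None = None
    rep: int | None = None


@dataclass
class PlotSet:
    """Plot boundary polygons with line/treatment/replicate metadata."""

    records: list[PlotRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.plot_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate plot_id(s): {dupes}")
        for r in self.records:
            if not r.polygon.is_valid:
                raise ValidationError(f"plot {r.plot_id}: polygon is not simple")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PlotRecord]:
        return iter(self.records)

    def __getitem__(self, plot_id: str) -> PlotRecord:
        for r in self.records:
            if r.plot_id == plot_id:
                return r
        raise KeyError(plot_id)

    @property
    def plot_ids(self) -> list[str]:
        return [r.plot_id for r in self.records]


def scale_dn_to_reflectance(dn):
    """Convert 16-bit digital numbers to reflectance (DN 32768 -> 1.0)."""
    arr = np.asarray(dn)
    if np.any(arr < 0) or np.any(arr > 65535):
        raise ValueError("digital numbers must lie in [0, 65535]")
    out = arr / DN_FULL_SCALE
    return float(out) if np.isscalar(dn) or arr.ndim == 0 else out


def _geo_tags(grid: GridGeometry, nodata=None) -> list[tuple]:
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (grid.px, grid.py, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0)),
    ]
    if nodata is not None:
        s = repr(nodata).encode() + b"\x00"
        tags.append((_TAG_GDAL_NODATA, "s", len(s), s))
    return tags


def _read_geo_tags(page) -> tuple[GridGeometry, float | None]:
    tags = page.tags
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise FormatError("raster is missing GeoTIFF georeferencing tags")
    sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value[:3]
    tie = tags[_TAG_MODEL_TIEPOINT].value
    i, j, _, x, y, _ = tie[:6]
    # tie point maps pixel corner (i, j) to world (x, y)
    x0 = x - i * sx
    y0 = y + j * sy
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00"))
    shp = page.shape[-2:] if len(page.shape) >= 2 else page.shape
    return GridGeometry(x0, y0, float(sx), float(sy), shp[0], shp[1]), nodata


def write_multiband_raster(
    stack: BandStack, path, encoding: str = "uint16_dn"
) -> None:
    """Write a 5-band GeoTIFF.

    ``uint16_dn`` clamps reflectance to [0, 65535/32768], rounds to the
    nearest DN and reserves DN 65535 as the nodata sentinel; ``float32``
    writes reflectance verbatim with NaN nodata.
    """
    path = Path(path)
    if encoding == "uint16_dn":
        nodata_mask = ~np.isfinite(stack.data)
        vals = np.where(nodata_mask, 0.0, stack.data)
        dn = np.rint(np.clip(vals, 0.0, 65534 / DN_FULL_SCALE) * DN_FULL_SCALE)
        dn = dn.astype(np.uint16)
        dn[nodata_mask] = 65535
        tifffile.imwrite(
            path, dn, photometric="minisblack", planarconfig="separate",
            extratags=_geo_tags(stack.grid, nodata=65535),
        )
    elif encoding == "float32":
        tifffile.imwrite(
            path, stack.data.astype(np.float32), photometric="minisblack",
            planarconfig="separate", extratags=_geo_tags(stack.grid, nodata=np.nan),
        )
    else:
        raise ValueError(f"unknown encoding {encoding!r}")


def read_multiband_raster(
    path, band_order: Sequence[BandDefinition] | Sequence[str] = REDEDGE_BANDS
) -> BandStack:
    """Read a multiband GeoTIFF into reflectance units.

    16-bit integer files are interpreted as digital numbers (32768 = 100 %);
    floating-point files pass through unchanged.
    """
    names = tuple(b.name if isinstance(b, BandDefinition) else str(b) for b in band_order)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        grid, nodata = _read_geo_tags(tif.pages[0])
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] != len(names):
        raise FormatError(
            f"band-count mismatch: file has {arr.shape[0]} bands, "
            f"expected {len(names)}"
        )
    if np.issubdtype(arr.dtype, np.integer):
        data = arr.astype(np.float64)
        if nodata is not None:
            data[arr == nodata] = np.nan
        mask = np.isnan(data)
        data = np.where(mask, 0, data)
        data = scale_dn_to_reflectance(data)
        data[mask] = np.nan
    else:
        data = arr.astype(np.float64)
        if nodata is not None and np.isfinite(nodata):
            data[arr == nodata] = np.nan
    grid = GridGeometry(grid.x0, grid.y0, grid.px, grid.py, arr.shape[-2], arr.shape[-1])
    return BandStack(data, grid, names)


def write_singleband_raster(arr: np.ndarray, grid: GridGeometry, path, dtype=np.float32,
                            nodata=None) -> None:
    arr = np.asarray(arr)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid geometry")
    tifffile.imwrite(
        Path(path), arr.astype(dtype), photometric="minisblack",
        extratags=_geo_tags(grid, nodata=nodata),
    )


def read_singleband_raster(path) -> tuple[np.ndarray, GridGeometry]:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        grid, nodata = _read_geo_tags(tif.pages[0])
    if arr.ndim != 2:
        raise FormatError("expected a single-band raster")
    if nodata is not None and np.issubdtype(arr.dtype, np.floating) and np.isfinite(nodata):
        arr = arr.astype(np.float64)
        arr[arr == nodata] = np.nan
    return arr, grid


def write_plot_polygons(plots: PlotSet, path) -> None:
    features = []
    for r in plots:
        props = {"plot_id": r.plot_id}
        if r.line is not None:
            props["line"] = r.line
        if r.treatment is not None:
            props["treatment"] = r.treatment
        if r.rep is not None:
            props["rep"] = r.rep
        features.append(
            {"type": "Feature", "geometry": mapping(r.polygon), "properties": props}
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )


def read_plot_polygons(path) -> PlotSet:
    """Read plot boundaries from GeoJSON (coordinates in metres).

    Raises :class:`ValidationError` for duplicate plot ids or non-polygon
    features.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise FormatError("expected a GeoJSON FeatureCollection")
    records = []
    for feat in doc.get("features", []):
        geom = shape(feat["geometry"])
        if not isinstance(geom, Polygon):
            raise ValidationError(
                f"non-polygon feature of type {geom.geom_type!r}"
            )
        props = feat.get("properties") or {}
        if "plot_id" not in props:
            raise ValidationError("feature without plot_id property")
        rep = props.get("rep")
        records.append(
            PlotRecord(
                plot_id=str(props["plot_id"]),
                polygon=geom,
                line=props.get("line"),
                treatment=props.get("treatment"),
                rep=int(rep) if rep is not None else None,
            )
        )
    return PlotSet(records)


def rasterize_plot(polygon: Polygon, grid: GridGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices (rows, cols) whose centers fall inside a polygon.

    Boundary pixels follow the half-open convention (west/north polygon
    edges inclusive): the test point is the pixel center nudged by a tiny
    epsilon east- and southwards, so adjacent plots never share a pixel.
    A polygon that does not overlap the grid yields empty index arrays.
    """
    minx, miny, maxx, maxy = polygon.bounds
    c0 = max(int(np.floor((minx - grid.x0) / grid.px)), 0)
    c1 = min(int(np.ceil((maxx - grid.x0) / grid.px)), grid.n_cols)
    r0 = max(int(np.floor((grid.y0 - maxy) / grid.py)), 0)
    r1 = min(int(np.ceil((grid.y0 - miny) / grid.py)), grid.n_rows)
    if c0 >= c1 or r0 >= r1:
        empty = np.empty(0, dtype=np.intp)
        return empty, empty
    eps_x = grid.px * 1e-9
    eps_y = grid.py * 1e-9
    xs = grid.x0 + (np.arange(c0, c1) + 0.5) * grid.px + eps_x
    ys = grid.y0 - (np.arange(r0, r1) + 0.5) * grid.py - eps_y
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.intersects_xy(polygon, xx.ravel(), yy.ravel()).reshape(xx.shape)
    rr, cc = np.nonzero(inside)
    return rr + r0, cc + c0
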