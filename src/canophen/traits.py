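"""Per-plot morphological and spectral trait extraction.

Plant height is the surface model minus a terrain model interpolated from
bare-soil strips flanking the field; per-plot height is summarized at the
90/93/95/98th percentiles of *all* pixels inside the plot boundary.  Canopy
cover is the fraction of plot pixels segmented as sunlit vegetation, and the
eight vegetation indices are averaged over sunlit-vegetation pixels only.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .geo_io import BandDefinition, BandStack, GridGeometry, PlotSet, rasterize_plot
from .segmentation import Mask, compute_exg, sunlit_vegetation_mask

__all__ = [
    "VI_NAMES",
    "HEIGHT_PERCENTILES",
    "InterpolationError",
    "estimate_dtm",
    "height_map",
    "plot_height_percentile",
    "canopy_cover",
    "compute_vi",
    "plot_mean_vi",
    "extract_plot_traits",
    "extract_scene_traits",
    "select_height_percentile",
    "resample_spectrum_to_bands",
]

log = logging.getLogger(__name__)

#: The eight vegetation indices, in reporting order.
VI_NAMES = ("exg", "ndvi", "rdvi", "gndvi", "ci_green", "ci_rededge", "ndre", "rgbvi")

#: Candidate plot-height percentiles.
HEIGHT_PERCENTILES = (90, 93, 95, 98)


class InterpolationError(ValueError):
    """Terrain interpolation failed (an empty margin strip on some row)."""


def estimate_dtm(
    dsm: np.ndarray,
    grid: GridGeometry,
    west_strip: Polygon,
    east_strip: Polygon,
) -> np.ndarray:
    """Terrain model from bare-soil strips on the east and west field edges.

    For every raster row the median surface elevation inside each strip is
    taken; elevation is then linearly interpolated across the row between the
    two strip centers, with constant extrapolation beyond them.  Assumes the
    terrain varies little along the north-south axis within a strip row.
    """
    dsm = np.asarray(dsm, dtype=float)
    if dsm.shape != grid.shape:
        raise ValueError("DSM shape does not match grid geometry")
    dtm = np.empty_like(dsm)
    cols = np.arange(grid.n_cols, dtype=float)
    strip_px = []
    for poly in (west_strip, east_strip):
        rr, cc = rasterize_plot(poly, grid)
        by_row: dict[int, list[int]] = {}
        for r, c in zip(rr, cc):
            by_row.setdefault(int(r), []).append(int(c))
        strip_px.append(by_row)
    for r in range(grid.n_rows):
        anchors = []
        for side, by_row in zip(("west", "east"), strip_px):
            cs = by_row.get(r, [])
            vals = dsm[r, cs]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                raise InterpolationError(
                    f"{side} margin strip has no valid pixel on row {r}"
                )
            anchors.append((float(np.mean(cs)), float(np.median(vals))))
        (cw, zw), (ce, ze) = anchors
        dtm[r] = np.interp(cols, [cw, ce], [zw, ze])
    return dtm


def height_map(dsm: np.ndarray, dtm: np.ndarray) -> np.ndarray:
    """Plant height in cm: (DSM - DTM) x 100, negatives clipped to zero."""
    dsm = np.asarray(dsm, dtype=float)
    dtm = np.asarray(dtm, dtype=float)
    if dsm.shape != dtm.shape:
        raise ValueError("DSM and DTM shapes differ")
    return np.clip((dsm - dtm) * 100.0, 0.0, None)


def plot_height_percentile(
    heights: np.ndarray, pixels: tuple[np.ndarray, np.ndarray], q: float
) -> float:
    """q-th percentile of all in-plot height pixels (vegetation and soil).

    Uses linear interpolation between order statistics.
    """
    rr, cc = pixels
    if len(rr) == 0:
        raise ValueError("plot pixel set is empty")
    vals = np.asarray(heights, dtype=float)[rr, cc]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("plot has no valid height pixels")
    return float(np.percentile(vals, q))


def canopy_cover(mask: Mask, pixels: tuple[np.ndarray, np.ndarray]) -> float:
    """Fraction of plot pixels that are sunlit vegetation."""
    rr, cc = pixels
    if len(rr) == 0:
        raise ValueError("plot pixel set is empty")
    return float(np.count_nonzero(mask.values[rr, cc])) / len(rr)


def compute_vi(stack: BandStack, name: str, printed_variant: bool = False) -> np.ndarray:
    """Per-pixel vegetation-index raster.

    Supported names: exg, ndvi, rdvi, gndvi, ci_green, ci_rededge, ndre,
    rgbvi.  RDVI uses the canonical renormalized form
    (rho_NIR - rho_Red)/sqrt(rho_NIR + rho_Red); ``printed_variant=True``
    selects the NDVI-identical variant some sources print with the square
    root dropped.  Division by zero yields NaN at that pixel.
    """
    name = name.lower()
    b = stack.band
    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "exg":
            return compute_exg(stack)
        if name == "ndvi":
            out = (b("nir") - b("red")) / (b("nir") + b("red"))
        elif name == "rdvi":
            if printed_variant:
                out = (b("nir") - b("red")) / (b("nir") + b("red"))
            else:
                out = (b("nir") - b("red")) / np.sqrt(b("nir") + b("red"))
        elif name == "gndvi":
            out = (b("nir") - b("green")) / (b("nir") + b("green"))
        elif name == "ci_green":
            out = b("nir") / b("green") - 1.0
        elif name == "ci_rededge":
            out = b("nir") / b("red_edge") - 1.0
        elif name == "ndre":
            out = (b("nir") - b("red_edge")) / (b("nir") + b("red_edge"))
        elif name == "rgbvi":
            g2 = b("green") ** 2
            br = b("blue") * b("red")
            out = (g2 - br) / (g2 + br)
        else:
            raise ValueError(f"unknown vegetation index {name!r}")
    return np.where(np.isfinite(out), out, np.nan)


def plot_mean_vi(
    vi: np.ndarray, mask: Mask, pixels: tuple[np.ndarray, np.ndarray]
) -> float:
    """Mean VI over pixels that are in-plot and sunlit vegetation.

    A plot with zero sunlit pixels yields NaN (a flagged missing value, not
    an exception) and is logged by the callers that aggregate plots.
    """
    rr, cc = pixels
    sel = mask.values[rr, cc]
    vals = np.asarray(vi, dtype=float)[rr[sel], cc[sel]]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def extract_plot_traits(
    stack: BandStack,
    mask: Mask,
    heights_cm: np.ndarray,
    heights_grid: GridGeometry,
    plots: PlotSet,
    printed_rdvi: bool = False,
) -> pd.DataFrame:
    """One row of traits per plot: height percentiles, cover, eight VI means.

    Height percentiles are computed on the (possibly finer) height grid; all
    spectral quantities on the multispectral grid.  Plots with zero pixels
    are flagged invalid; plots with zero sunlit pixels get NaN VI means.
    """
    vi_rasters = {
        name: compute_vi(stack, name, printed_variant=(printed_rdvi and name == "rdvi"))
        for name in VI_NAMES
    }
    rows = []
    n_flagged = 0
    for rec in plots:
        ms_px = rasterize_plot(rec.polygon, stack.grid)
        h_px = rasterize_plot(rec.polygon, heights_grid)
        row: dict = {
            "plot_id": rec.plot_id,
            "line": rec.line,
            "treatment": rec.treatment,
            "rep": rec.rep,
        }
        if len(ms_px[0]) == 0 or len(h_px[0]) == 0:
            row.update({"valid": False, "n_pixels": 0, "n_sunlit": 0})
            rows.append(row)
            n_flagged += 1
            continue
        for q in HEIGHT_PERCENTILES:
            row[f"ph{q}"] = plot_height_percentile(heights_cm, h_px, q)
        n_pixels = len(ms_px[0])
        n_sunlit = int(np.count_nonzero(mask.values[ms_px]))
        row["cc"] = canopy_cover(mask, ms_px)
        for name in VI_NAMES:
            row[name] = plot_mean_vi(vi_rasters[name], mask, ms_px)
        row.update({"n_pixels": n_pixels, "n_sunlit": n_sunlit, "valid": True})
        if n_sunlit == 0:
            log.warning("plot %s has zero sunlit vegetation pixels", rec.plot_id)
        rows.append(row)
    if n_flagged:
        log.warning("%d plot(s) had no pixels and were flagged invalid", n_flagged)
    return pd.DataFrame(rows)


def extract_scene_traits(scene, threshold: float | None = None) -> pd.DataFrame:
    """Convenience wrapper: segment a scene, build its DTM, extract traits."""
    from .scene_sim import margin_strip_polygons

    cfg = scene.config
    thr = cfg.exg_threshold if threshold is None else threshold
    mask = sunlit_vegetation_mask(scene.bands, thr)
    west, east = margin_strip_polygons(scene.plots, cfg.margin_strip_m)
    dtm = estimate_dtm(scene.dsm, scene.dsm_grid, west, east)
    heights = height_map(scene.dsm, dtm)
    return extract_plot_traits(scene.bands, mask, heights, scene.dsm_grid, scene.plots)


def select_height_percentile(
    traits: pd.DataFrame,
    measured: pd.Series | Mapping[str, float] | pd.DataFrame,
    percentiles: Sequence[int] = HEIGHT_PERCENTILES,
) -> tuple[int, pd.Series]:
    """Percentile whose plot heights correlate best with manual measurements.

    ``measured`` maps plot_id to measured height (cm).  Returns the winning
    percentile (ties broken toward the lower one) and the full Pearson-r
    table.
    """
    from .models import pearson_r

    if isinstance(measured, pd.DataFrame):
        measured = measured.set_index("plot_id").iloc[:, 0]
    elif isinstance(measured, Mapping):
        measured = pd.Series(measured)
    df = traits.set_index("plot_id")
    common = df.index.intersection(measured.index)
    if len(common) < 3:
        raise ValueError("need at least 3 plots with both values")
    m = measured.loc[common].to_numpy(dtype=float)
    rs = {}
    for q in percentiles:
        rs[q] = pearson_r(m, df.loc[common, f"ph{q}"].to_numpy(dtype=float))[0]
    table = pd.Series(rs, name="r")
    best = max(sorted(table.index), key=lambda q: (table[q], -q))
    return int(best), table


def resample_spectrum_to_bands(
    wavelengths_nm: np.ndarray,
    reflectance: np.ndarray,
    bands: Sequence[BandDefinition],
) -> dict[str, float]:
    """Band-average a (hyperspectral) spectrum to multispectral reflectances.

    Each band applies a Gaussian response centered at ``center_nm`` with the
    stated FWHM, truncated at +/-1.5 FWHM, integrated by the trapezoid rule
    on the spectrum's own wavelength grid.
    """
    wl = np.asarray(wavelengths_nm, dtype=float)
    refl = np.asarray(reflectance, dtype=float)
    if wl.ndim != 1 or wl.shape != refl.shape:
        raise ValueError("wavelengths and reflectance must be equal-length vectors")
    order = np.argsort(wl)
    wl, refl = wl[order], refl[order]
    out = {}
    for band in bands:
        lo = band.center_nm - 1.5 * band.fwhm_nm
        hi = band.center_nm + 1.5 * band.fwhm_nm
        if wl[0] > lo or wl[-1] < hi:
            raise ValueError(f"spectrum does not cover band {band.name!r} support")
        sel = (wl >= lo) & (wl <= hi)
        if np.any(np.diff(wl[sel]) > band.fwhm_nm):
            raise ValueError(f"spectrum gap inside band {band.name!r} support")
        # include the exact truncation endpoints for a clean integral
        grid = np.unique(np.concatenate([wl[sel], [lo, hi]]))
        r = np.interp(grid, wl, refl)
        sigma = band.fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        w = np.exp(-0.5 * ((grid - band.center_nm) / sigma) ** 2)
        out[band.name] = float(np.trapezoid(r * w, grid) / np.trapezoid(w, grid))
    return out
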