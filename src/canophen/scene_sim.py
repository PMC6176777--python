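"""Synthetic field scenes with known ground truth.

Emulates a randomized-complete-block nitrogen trial (default 24 lines x 2
treatments x 8 replicates = 384 plots of 3 m x 3 m, four crop rows per plot)
imaged by a 5-band multispectral camera and a photogrammetric surface model:

* plot polygons on a regular grid, lines randomized within replicate blocks,
  flanked east and west by bare-soil margin strips;
* per-plot ground truth (height, cover, spectral latents, fresh/dry biomass
  linked to traits through exponential models with multiplicative log-normal
  noise, leaf nitrogen and chlorophyll correlated with the red-edge latent);
* rendered reflectance rasters (canopy rows as flat-topped strips over a
  soil background), a digital surface model on a finer grid, a per-pixel
  class-label raster, and geometric cast shadows whose differential
  attenuation (visible light suppressed much more strongly than NIR)
  reproduces the counter-intuitive field artifact that shaded pixels show
  *higher* NDVI than sunlit canopy while their ExG drops below the
  vegetation-segmentation threshold.

All randomness flows from one root seed through named substreams (design,
truths, render, shadows) so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from . import reference
from .geo_io import (
    BandStack,
    GridGeometry,
    PlotRecord,
    PlotSet,
    rasterize_plot,
    read_multiband_raster,
    read_plot_polygons,
    read_singleband_raster,
    write_multiband_raster,
    write_plot_polygons,
    write_singleband_raster,
)
from .models import ExponentialModel, predict

__all__ = [
    "LABELS",
    "LABEL_NAMES",
    "SOIL_SPECTRUM",
    "VEG_NIR",
    "NoiseParams",
    "SceneConfig",
    "Scene",
    "GeometryError",
    "build_field_design",
    "margin_strip_polygons",
    "simulate_plot_truths",
    "latent_predictor_frame",
    "render_scene",
    "cast_shadows",
    "simulate_scene",
    "save_scene",
    "load_scene",
]

#: Per-pixel class codes in the label raster.
LABELS = {"soil_sunlit": 0, "soil_shaded": 1, "veg_sunlit": 2, "veg_shaded": 3}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: Bare-soil reflectance: a nearly flat, slightly red-tilted spectrum, so its
#: ExG sits just below zero and its sunlit NDVI stays modest.
SOIL_SPECTRUM = {"blue": 0.09, "green": 0.11, "red": 0.14, "red_edge": 0.20, "nir": 0.28}

#: Sunlit-canopy NIR reflectance (held fixed; the visible and red-edge bands
#: are solved per plot from the latent index values).
VEG_NIR = 0.45

_STAGES = ("design", "truths", "render", "shadows")


class GeometryError(ValueError):
    """A plot polygon falls outside the raster extent."""


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES.index(stage)]))


@dataclass(frozen=True)
class NoiseParams:
    """Explicit noise levels of the forward model (all >= 0)."""

    biomass_log_sd: float = 0.10   # sd of ln(noise) on biomass (multiplicative)
    reflectance_sd: float = 0.003  # additive reflectance noise per band
    height_sd_m: float = 0.05      # within-plot canopy-top jitter

    def __post_init__(self) -> None:
        if min(self.biomass_log_sd, self.reflectance_sd, self.height_sd_m) < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass(frozen=True)
class SceneConfig:
    """Study-design and forward-model parameters of a simulated field."""

    n_lines: int = 24
    n_treatments: int = 2
    n_reps: int = 8
    plot_size_m: float = 3.0
    row_spacing_m: float = 0.76
    rows_per_plot: int = 4
    gsd_ms_m: float = 0.020    # multispectral ground sampling distance
    gsd_rgb_m: float = 0.013   # surface-model / RGB ground sampling distance
    margin_strip_m: float = 2.0
    sun_azimuth_deg: float = 225.0   # sun position (compass); shadows fall NE
    sun_elevation_deg: float = 65.0  # midsummer midday at mid-latitudes
    exg_threshold: float = 0.046
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    # ground-truth distributions (late-season energy sorghum, 3.5-4.5 m tall)
    height_range_cm: tuple[float, float] = (350.0, 450.0)
    cover_range: tuple[float, float] = (0.5, 0.9)
    ndvi_range: tuple[float, float] = (0.60, 0.80)
    ndre_range: tuple[float, float] = (0.25, 0.40)
    ndre_treatment_shift: float = 0.08   # added to high-N plots' NDRE latent
    green_treatment_shift: float = 0.004  # subtracted from high-N veg green
    lab_correlation: float = 0.6         # latent NDRE vs leaf N / chlorophyll
    veg_green_range: tuple[float, float] = (0.125, 0.138)
    veg_blue_range: tuple[float, float] = (0.045, 0.055)
    # terrain
    base_elevation_m: float = 100.0
    ew_slope: float = 0.005      # terrain rise per metre eastwards
    # shadow attenuation factors
    visible_attenuation: float = 0.2
    nir_attenuation: float = 0.7

    def __post_init__(self) -> None:
        for name in ("n_lines", "n_treatments", "n_reps", "rows_per_plot"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.gsd_ms_m <= 0 or self.gsd_rgb_m <= 0 or self.plot_size_m <= 0:
            raise ValueError("plot size and GSDs must be positive")
        if not 0 < self.sun_elevation_deg <= 90:
            raise ValueError("sun_elevation_deg must be in (0, 90]")
        if self.margin_strip_m < 0:
            raise ValueError("margin_strip_m must be >= 0")

    @property
    def n_plots(self) -> int:
        return self.n_lines * self.n_treatments * self.n_reps

    def to_yaml(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseParams(**d["noise"])
        for key in ("height_range_cm", "cover_range", "ndvi_range", "ndre_range",
                    "veg_green_range", "veg_blue_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Scene:
    """A simulated (or reloaded) field ready for trait extraction."""

    bands: BandStack
    labels: np.ndarray | None      # class codes on the multispectral grid
    dsm: np.ndarray                # surface elevation, metres, fine grid
    dsm_grid: GridGeometry
    dtm_true: np.ndarray           # true terrain on the fine grid
    plots: PlotSet
    truth: pd.DataFrame
    config: SceneConfig
    surface_ms: np.ndarray | None = None  # surface elevation on the MS grid


def build_field_design(config: SceneConfig, seed: int | None = None) -> PlotSet:
    """Lay out the trial: one block per replicate, lines randomized in block.

    Each block is an ``n_treatments`` x ``n_lines`` grid of plots; blocks are
    stacked north to south; all line-by-treatment combinations are shuffled
    independently within every block (randomized complete block design).
    Bare-soil margin strips of ``margin_strip_m`` flank the field east and
    west (see :func:`margin_strip_polygons`).
    """
    rng = _stage_rng(config.seed if seed is None else seed, "design")
    w = config.plot_size_m
    x_off = config.margin_strip_m
    lines = [f"L{i + 1:02d}" for i in range(config.n_lines)]
    treatments = ["high_N", "low_N"][: config.n_treatments] or ["high_N"]
    if config.n_treatments > 2:
        treatments = [f"T{i + 1}" for i in range(config.n_treatments)]
    records = []
    per_block = config.n_lines * config.n_treatments
    for rep in range(1, config.n_reps + 1):
        combos = [(ln, tr) for tr in treatments for ln in lines]
        order = rng.permutation(per_block)
        for slot, idx in enumerate(order):
            line, treatment = combos[idx]
            row_in_block, col = divmod(slot, config.n_lines)
            row = (rep - 1) * config.n_treatments + row_in_block
            x0 = x_off + col * w
            # y decreases southwards; row 0 is the northernmost strip of plots
            y_top = -row * w
            poly = box(x0, y_top - w, x0 + w, y_top)
            records.append(
                PlotRecord(
                    plot_id=f"P{len(records) + 1:03d}",
                    polygon=poly,
                    line=line,
                    treatment=treatment,
                    rep=rep,
                )
            )
    return PlotSet(records)


def margin_strip_polygons(plots: PlotSet, margin_strip_m: float):
    """(west, east) bare-soil strip polygons flanking the plot extent."""
    minx = min(r.polygon.bounds[0] for r in plots)
    maxx = max(r.polygon.bounds[2] for r in plots)
    miny = min(r.polygon.bounds[1] for r in plots)
    maxy = max(r.polygon.bounds[3] for r in plots)
    # strips overshoot the plot extent north/south so that every raster row
    # (grids round up to a whole pixel) intersects both strips
    pad = 1.0
    west = box(minx - margin_strip_m, miny - pad, minx, maxy + pad)
    east = box(maxx, miny - pad, maxx + margin_strip_m, maxy + pad)
    return west, east


def latent_predictor_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """Candidate-predictor values implied by each plot's latent truth.

    PH is the true height (cm), CC the true cover fraction, and the
    vegetation indices are the values of the sunlit-canopy spectrum implied
    by the latent NDVI/NDRE and the per-plot green/blue reflectances.
    """
    v = truth["ndvi_latent"].to_numpy(float)
    g = truth["veg_green"].to_numpy(float)
    b = truth["veg_blue"].to_numpy(float)
    red = VEG_NIR * (1 - v) / (1 + v)
    return pd.DataFrame(
        {
            "PH": truth["true_height_cm"].to_numpy(float),
            "CC": truth["true_cover"].to_numpy(float),
            "NDVI": v,
            "NDRE": truth["ndre_latent"].to_numpy(float),
            "RDVI": (VEG_NIR - red) / np.sqrt(VEG_NIR + red),
            "RGBVI": (g**2 - b * red) / (g**2 + b * red),
        },
        index=truth.index,
    )


def simulate_plot_truths(
    design: PlotSet,
    config: SceneConfig,
    seed: int | None = None,
    fresh_model: ExponentialModel | None = None,
    dry_model: ExponentialModel | None = None,
) -> pd.DataFrame:
    """Draw per-plot ground truth consistent with the generative models.

    Heights combine a per-line mean with plot scatter; the NDRE latent of
    high-nitrogen plots is shifted up by ``ndre_treatment_shift``; biomass is
    the exponential model prediction times log-normal noise
    (``ln eps ~ N(0, biomass_log_sd^2)``); leaf nitrogen and chlorophyll are
    drawn with Pearson correlation ``lab_correlation`` to the NDRE latent.
    """
    fresh_model = fresh_model or reference.DEFAULT_FRESH_MODEL
    dry_model = dry_model or reference.DEFAULT_DRY_MODEL
    if fresh_model.a <= 0 or dry_model.a <= 0:
        raise ValueError("generative models need a positive multiplicative coefficient")
    rng = _stage_rng(config.seed if seed is None else seed, "truths")
    n = len(design)
    lines = sorted({r.line for r in design})
    h_lo, h_hi = config.height_range_cm
    line_means = {
        ln: rng.uniform(min(h_lo + 30, h_hi), max(h_lo, h_hi - 30)) for ln in lines
    }
    rows = []
    for rec in design:
        h = np.clip(line_means[rec.line] + rng.normal(0.0, 15.0), h_lo, h_hi)
        rows.append((rec.plot_id, rec.line, rec.treatment, rec.rep, float(h)))
    truth = pd.DataFrame(
        rows, columns=["plot_id", "line", "treatment", "rep", "true_height_cm"]
    )
    truth["true_cover"] = rng.uniform(*config.cover_range, size=n)
    truth["ndvi_latent"] = rng.uniform(*config.ndvi_range, size=n)
    shift = np.where(truth["treatment"] == "high_N", config.ndre_treatment_shift, 0.0)
    truth["ndre_latent"] = rng.uniform(*config.ndre_range, size=n) + shift
    # higher chlorophyll also darkens the green band, so the green-based
    # chlorophyll indices separate by treatment as well
    g_shift = np.where(
        truth["treatment"] == "high_N", config.green_treatment_shift, 0.0
    )
    truth["veg_green"] = rng.uniform(*config.veg_green_range, size=n) - g_shift
    truth["veg_blue"] = rng.uniform(*config.veg_blue_range, size=n)

    X = latent_predictor_frame(truth)
    sd = config.noise.biomass_log_sd
    fresh = predict(fresh_model, X) * np.exp(rng.normal(0.0, sd, size=n))
    dry = predict(dry_model, X) * np.exp(rng.normal(0.0, sd, size=n))
    truth["fresh_biomass_kg"] = fresh
    truth["dry_biomass_kg"] = np.minimum(dry, 0.95 * fresh)

    # leaf traits share a standardized component with the NDRE latent
    u = truth["ndre_latent"].to_numpy(float)
    su = u.std()
    zu = (u - u.mean()) / su if su > 0 else np.zeros(n)
    rho = config.lab_correlation
    mix = math.sqrt(max(0.0, 1 - rho**2))
    truth["leaf_N_pct"] = 2.6 + 0.5 * (rho * zu + mix * rng.normal(size=n))
    truth["chlorophyll"] = 35.0 + 8.0 * (rho * zu + mix * rng.normal(size=n))
    return truth


def _make_grid(design: PlotSet, margin: float, gsd: float,
               extent: tuple[float, float, float, float] | None = None) -> GridGeometry:
    if extent is None:
        minx = min(r.polygon.bounds[0] for r in design) - margin
        maxx = max(r.polygon.bounds[2] for r in design) + margin
        miny = min(r.polygon.bounds[1] for r in design)
        maxy = max(r.polygon.bounds[3] for r in design)
    else:
        minx, miny, maxx, maxy = extent
    n_cols = int(math.ceil((maxx - minx) / gsd - 1e-9))
    n_rows = int(math.ceil((maxy - miny) / gsd - 1e-9))
    return GridGeometry(minx, maxy, gsd, gsd, n_rows, n_cols)


def _terrain(grid: GridGeometry, config: SceneConfig) -> np.ndarray:
    xs = grid.col_centers()
    return np.broadcast_to(
        config.base_elevation_m + config.ew_slope * (xs - grid.x0),
        grid.shape,
    ).copy()


def _veg_columns(rec: PlotRecord, cover: float, config: SceneConfig,
                 xs: np.ndarray) -> np.ndarray:
    """Boolean mask over pixel-center x positions: inside a canopy row strip."""
    x0, _, x1, _ = rec.polygon.bounds
    w = x1 - x0
    n_rows = config.rows_per_plot
    half = cover * w / (2 * n_rows)
    centers = x0 + (np.arange(n_rows) + 0.5) * w / n_rows
    d = np.abs(xs[:, None] - centers[None, :]).min(axis=1)
    # closed comparison so that full cover (strip edges meeting exactly
    # midway between rows) leaves no one-pixel soil seams
    return d <= half + 1e-9


def render_scene(
    design: PlotSet,
    truth: pd.DataFrame,
    config: SceneConfig,
    seed: int | None = None,
    extent: tuple[float, float, float, float] | None = None,
) -> Scene:
    """Forward-render reflectance, surface model and labels (no shadows yet).

    Canopy rows are flat-topped strips at the plot's true height (with
    per-pixel vertical jitter) whose total width fraction equals the plot's
    true cover; vegetation band reflectances are solved from the plot's
    latent NDVI/NDRE; soil gets a flat spectrum; additive Gaussian
    reflectance noise is applied to every band.
    """
    missing = set(design.plot_ids) - set(truth["plot_id"])
    if missing:
        raise ValueError(f"truth table lacks plots: {sorted(missing)[:5]}")
    rng = _stage_rng(config.seed if seed is None else seed, "render")
    ms = _make_grid(design, config.margin_strip_m, config.gsd_ms_m, extent)
    hg = _make_grid(design, config.margin_strip_m, config.gsd_rgb_m, extent)
    for rec in design:
        if not ms.contains_polygon(rec.polygon) or not hg.contains_polygon(rec.polygon):
            raise GeometryError(f"plot {rec.plot_id} falls outside the raster extent")

    bands = np.empty((5, *ms.shape), dtype=np.float64)
    for i, name in enumerate(("blue", "green", "red", "red_edge", "nir")):
        bands[i].fill(SOIL_SPECTRUM[name])
    labels = np.full(ms.shape, LABELS["soil_sunlit"], dtype=np.uint8)
    dtm_ms = _terrain(ms, config)
    dtm_h = _terrain(hg, config)
    canopy_ms = np.zeros(ms.shape)
    canopy_h = np.zeros(hg.shape)
    xs_ms, xs_h = ms.col_centers(), hg.col_centers()
    t = truth.set_index("plot_id")

    for rec in design:
        row = t.loc[rec.plot_id]
        v, u = float(row["ndvi_latent"]), float(row["ndre_latent"])
        spectrum = np.array(
            [
                float(row["veg_blue"]),
                float(row["veg_green"]),
                VEG_NIR * (1 - v) / (1 + v),
                VEG_NIR * (1 - u) / (1 + u),
                VEG_NIR,
            ]
        )
        h_m = float(row["true_height_cm"]) / 100.0
        for grid, xs, canopy in ((ms, xs_ms, canopy_ms), (hg, xs_h, canopy_h)):
            rr, cc = rasterize_plot(rec.polygon, grid)
            if rr.size == 0:
                continue
            veg = _veg_columns(rec, float(row["true_cover"]), config, xs[cc])
            vr, vc = rr[veg], cc[veg]
            if grid is ms:
                # the MS-grid surface keeps the nominal flat canopy top so
                # that equal-height neighbouring rows do not shade each other
                labels[vr, vc] = LABELS["veg_sunlit"]
                bands[:, vr, vc] = spectrum[:, None]
                canopy[vr, vc] = h_m
            else:
                jitter = rng.normal(0.0, config.noise.height_sd_m, size=vr.size)
                canopy[vr, vc] = np.maximum(h_m + jitter, 0.0) if h_m > 0 else 0.0

    if config.noise.reflectance_sd > 0:
        bands += rng.normal(0.0, config.noise.reflectance_sd, size=bands.shape)
        np.clip(bands, 0.0, None, out=bands)
    stack = BandStack(bands, ms)
    return Scene(
        bands=stack,
        labels=labels,
        dsm=dtm_h + canopy_h,
        dsm_grid=hg,
        dtm_true=dtm_h,
        plots=design,
        truth=truth.reset_index(drop=True),
        config=config,
        surface_ms=dtm_ms + canopy_ms,
    )


def _shadow_mask(surface: np.ndarray, grid: GridGeometry,
                 azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Binary cast-shadow mask by ray-casting toward the sun over the surface."""
    if elevation_deg >= 90:
        return np.zeros(surface.shape, dtype=bool)
    az = math.radians(azimuth_deg)
    ux, uy = math.sin(az), math.cos(az)  # horizontal unit vector toward the sun
    step = min(grid.px, grid.py)
    drop = step * math.tan(math.radians(elevation_deg))
    span = float(surface.max() - surface.min())
    kmax = int(math.ceil(span / drop)) if drop > 0 else 0
    best = np.full(surface.shape, -np.inf)
    n_rows, n_cols = surface.shape
    for k in range(1, kmax + 1):
        dc = int(round(k * step * ux / grid.px))
        dr = int(round(-k * step * uy / grid.py))
        if abs(dr) >= n_rows or abs(dc) >= n_cols:
            break
        shifted = np.full(surface.shape, -np.inf)
        src_r = slice(max(dr, 0), n_rows + min(dr, 0))
        dst_r = slice(max(-dr, 0), n_rows + min(-dr, 0))
        src_c = slice(max(dc, 0), n_cols + min(dc, 0))
        dst_c = slice(max(-dc, 0), n_cols + min(-dc, 0))
        shifted[dst_r, dst_c] = surface[src_r, src_c]
        np.maximum(best, shifted - k * drop, out=best)
    return best > surface + 1e-9


def cast_shadows(scene: Scene, config: SceneConfig | None = None) -> Scene:
    """Project shadows from the canopy surface and attenuate shaded pixels.

    Pixels lying in the geometric shadow of taller canopy (ray-cast from the
    configured sun azimuth/elevation) are relabelled ``*_shaded``; their
    visible bands are multiplied by ``visible_attenuation`` and the
    red-edge/NIR bands by ``nir_attenuation``.  Because the visible bands are
    suppressed far more strongly, shaded-pixel NDVI rises above sunlit-canopy
    NDVI while shaded ExG collapses below the segmentation threshold.
    """
    config = config or scene.config
    if scene.labels is None:
        raise ValueError("scene has no label raster; render it first")
    if scene.surface_ms is None:
        raise ValueError("scene has no canopy surface on the multispectral grid")
    shaded = _shadow_mask(
        scene.surface_ms, scene.bands.grid,
        config.sun_azimuth_deg, config.sun_elevation_deg,
    )
    labels = scene.labels.copy()
    labels[shaded & (labels == LABELS["soil_sunlit"])] = LABELS["soil_shaded"]
    labels[shaded & (labels == LABELS["veg_sunlit"])] = LABELS["veg_shaded"]
    data = scene.bands.data.copy()
    for i in (0, 1, 2):
        data[i][shaded] *= config.visible_attenuation
    for i in (3, 4):
        data[i][shaded] *= config.nir_attenuation
    return replace(
        scene, bands=BandStack(data, scene.bands.grid, scene.bands.band_names),
        labels=labels,
    )


def simulate_scene(
    config: SceneConfig,
    seed: int | None = None,
    fresh_model: ExponentialModel | None = None,
    dry_model: ExponentialModel | None = None,
) -> Scene:
    """Full pipeline: design -> truths -> render -> cast shadows."""
    seed = config.seed if seed is None else seed
    design = build_field_design(config, seed)
    truth = simulate_plot_truths(design, config, seed, fresh_model, dry_model)
    scene = render_scene(design, truth, config, seed)
    return cast_shadows(scene, config)


def save_scene(scene: Scene, out_dir) -> dict:
    """Write scene artifacts (GeoTIFF/GeoJSON/CSV/YAML) plus a manifest.

    Returns the manifest mapping file names to SHA-256 content hashes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_multiband_raster(scene.bands, out / "stack.tif", encoding="uint16_dn")
    write_singleband_raster(scene.dsm, scene.dsm_grid, out / "dsm.tif")
    write_singleband_raster(scene.dtm_true, scene.dsm_grid, out / "dtm_true.tif")
    if scene.labels is not None:
        write_singleband_raster(
            scene.labels, scene.bands.grid, out / "labels.tif", dtype=np.uint8
        )
    write_plot_polygons(scene.plots, out / "plots.geojson")
    west, east = margin_strip_polygons(scene.plots, scene.config.margin_strip_m)
    margins = PlotSet(
        [PlotRecord("west_margin", west), PlotRecord("east_margin", east)]
    )
    write_plot_polygons(margins, out / "margins.geojson")
    scene.truth.to_csv(out / "truth.csv", index=False)
    scene.config.to_yaml(out / "config.yaml")
    manifest = {}
    for f in sorted(out.iterdir()):
        if f.name == "manifest.json" or f.is_dir():
            continue
        manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_scene(scene_dir) -> Scene:
    """Reload a saved scene directory (labels optional, surface not kept)."""
    d = Path(scene_dir)
    config = SceneConfig.from_yaml(d / "config.yaml")
    stack = read_multiband_raster(d / "stack.tif")
    dsm, dsm_grid = read_singleband_raster(d / "dsm.tif")
    dtm_true, _ = read_singleband_raster(d / "dtm_true.tif")
    labels = None
    if (d / "labels.tif").exists():
        labels, _ = read_singleband_raster(d / "labels.tif")
        labels = labels.astype(np.uint8)
    plots = read_plot_polygons(d / "plots.geojson")
    truth = pd.read_csv(d / "truth.csv")
    return Scene(
        bands=stack, labels=labels, dsm=np.asarray(dsm, float), dsm_grid=dsm_grid,
        dtm_true=np.asarray(dtm_true, float), plots=plots, truth=truth, config=config,
    )
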