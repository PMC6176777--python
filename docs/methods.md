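# Methods

This note documents the models behind `canophen`: what the synthetic scene
generator emulates, how each analysis stage is defined, the parameters that
matter, and the numerical choices made where several defensible options
existed.

## The forward model (scene_sim)

### Field design

`build_field_design` lays out a randomized complete block trial: one block
per replicate, each block an `n_treatments x n_lines` grid of square plots,
blocks stacked north to south. All line-by-treatment combinations are
shuffled independently within every block, so treatments are randomized
within replicates as in a standard RCBD. Defaults (24 lines, 2 nitrogen
treatments, 8 replicates, 3 m plots, 4 crop rows at 0.76 m spacing) match
the sorghum trial the analysis was designed around, for 384 plots in a
~72 m x 48 m field flanked east and west by 2 m bare-soil strips.

### Ground truth

Per plot, `simulate_plot_truths` draws:

* **Plant height** — a per-line mean, uniform on the inner part of
  `height_range_cm`, plus N(0, 15 cm) plot scatter. The default range
  350–450 cm describes the late-season energy-sorghum crop the analysis
  targets ("over 3.5 to 4.5 m"); it also keeps height contrasts between
  neighbouring plots moderate, which bounds how much one plot's canopy can
  shade another's (see *Shadows* below).
* **Canopy cover** — uniform on (0.5, 0.9).
* **Spectral latents** — NDVI uniform on (0.60, 0.80) and NDRE uniform on
  (0.25, 0.40); high-nitrogen plots get `ndre_treatment_shift` (+0.08)
  added to NDRE and `green_treatment_shift` (0.004) subtracted from their
  green reflectance, so the chlorophyll-sensitive indices (NDRE,
  CI_rededge, and via green also CI_green/GNDVI) separate by treatment.
  Per-plot green and blue reflectances vary independently in narrow bands
  so that RGBVI and GNDVI are not deterministic functions of NDVI.
* **Biomass** — fresh and dry biomass are exponential functions of the
  latent traits times multiplicative log-normal noise,
  `Y = a e^(Σ bⱼxⱼ) · ε`, `ln ε ~ N(0, biomass_log_sd²)` (default sd 0.10).
  The default generative links are the published plant-height calibrations
  shipped in `reference.py` (fresh: a = 21.22, b = 0.005 per cm; dry:
  a = 5.63, b = 0.004); any `ExponentialModel` over
  {PH, CC, NDVI, NDRE, RDVI, RGBVI} can be substituted. Dry biomass is
  capped at 0.95 x fresh so the physical ordering always holds.
* **Leaf chemistry** — leaf N (%) and chlorophyll share a standardized
  component with the NDRE latent at Pearson correlation `lab_correlation`
  (default 0.6), the rest being independent Gaussian noise. Units are
  arbitrary-but-plausible (leaf N around 2.6 %, chlorophyll around 35).

### Rendering

Canopy is rendered as flat-topped strips: each plot's four crop rows are
vertical strips whose total width fraction equals the plot's true cover, at
the plot's true height. The multispectral stack (default 2 cm GSD) gets a
five-value spectrum per pixel: a fixed slightly red-tilted soil spectrum
(0.09/0.11/0.14/0.20/0.28 across blue→NIR), or the plot's canopy spectrum,
which holds NIR at 0.45 and solves red and red-edge from the latent NDVI
and NDRE (ρ = ρ_NIR(1−v)/(1+v)). Additive Gaussian reflectance noise
(default sd 0.003) is applied to every band. The surface model (default
1.3 cm GSD) is the true terrain — a gentle east-west plane, 0.005 m/m —
plus the canopy height with per-pixel N(0, `height_sd_m`) jitter (default
5 cm) on vegetation pixels. A label raster records every multispectral
pixel as sunlit/shaded soil/vegetation.

### Shadows

`cast_shadows` ray-casts from the configured sun position (default azimuth
225°, elevation 65° — mid-afternoon midsummer at mid-latitudes) over the
canopy surface on the multispectral grid: a pixel is shaded when any point
along the ray toward the sun rises above the sight line at that pixel's
elevation. Shaded pixels are relabelled and their reflectances attenuated
— visible bands x0.2, red-edge and NIR x0.7 (red-edge grouped with NIR as
long-wavelength). Diffuse skylight is relatively NIR-rich, which is why
shadow suppresses the visible bands far more strongly; the two factors are
chosen so that the generator reproduces the field artifact the
segmentation stage exists to handle:

* shaded NDVI rises above sunlit-canopy NDVI (shaded soil ≈ 0.75, shaded
  canopy ≈ 0.9, versus sunlit canopy ≈ 0.70), and
* shaded ExG falls to 0.2 x its sunlit value, well below the 0.046
  segmentation threshold (sunlit canopy ExG is ≈ 0.09–0.19 by
  construction of the canopy spectra, so 4–5 σ of reflectance noise still
  cannot push a shaded pixel over the threshold, nor a sunlit canopy pixel
  under it).

The shadow surface uses the *nominal* flat canopy top, not the jittered
one: with per-pixel jitter, two equal-height neighbouring rows would shade
each other on ~half their pixels purely by noise, which has no physical
counterpart (real canopy-top roughness is spatially correlated) and would
bias canopy cover low by tens of percent. Jitter therefore lives only on
the fine surface-model grid, where it matters for the height percentiles.
Residual cross-plot shading of genuinely shorter plots by taller
neighbours remains, which is why cover recovery is specified per-plot
within ±0.05 for ≥90 % of plots rather than for all.

## The analysis stages

* **ExG segmentation** (`segmentation`) — mask = ExG strictly greater than
  the threshold (pixels exactly at threshold are background, matching the
  filter's intent of excluding low values). ExG is computed from the
  multispectral blue/green/red bands because the mask is applied to index
  rasters on that grid. No morphological cleanup is applied: the procedure
  is pure thresholding.
* **Terrain model** (`traits.estimate_dtm`) — per raster row, the median
  surface elevation inside each flanking soil strip, linearly interpolated
  across the row between strip centers, constant beyond them. A strip row
  with no valid pixel is an error naming the row. This assumes terrain
  varies smoothly east-west and negligibly within a strip row.
* **Heights** — (DSM − DTM) x 100, clipped at 0 cm (DTM interpolation can
  produce small negatives over soil). Plot percentiles are taken over
  *all* in-plot pixels, soil included, with linear interpolation between
  order statistics (`numpy.percentile` default); with ≥50 % cover the 90th
  percentile lands on canopy. `select_height_percentile` picks the
  percentile with the highest Pearson r against measured heights, ties
  broken toward the lower percentile.
* **Vegetation indices** — the eight standard formulas; division by zero
  yields a flagged missing pixel. RDVI is the renormalized form
  (ρ_NIR − ρ_R)/√(ρ_NIR + ρ_R); a `printed_variant` flag reproduces the
  NDVI-identical variant that appears in some published tables with the
  radical dropped. Plot means are taken over in-plot, mask-true pixels
  only; a plot with zero sunlit pixels gets NaN and a log entry, not an
  exception.
* **Zonal membership** (`geo_io.rasterize_plot`) — a pixel belongs to a
  plot iff its center is inside the polygon, with a half-open boundary
  rule (west/north edges inclusive, implemented by nudging the test point
  one part in 10⁹ of a pixel east/south), so adjacent plots partition the
  grid exactly.
* **Band resampling** (`traits.resample_spectrum_to_bands`) — Gaussian
  spectral response per band (σ = FWHM/2.355) truncated at ±1.5 FWHM,
  integrated by the trapezoid rule on the spectrum's own grid; used to
  reduce leaf-level hyperspectral measurements to camera-equivalent band
  reflectances.

## Modelling choices (models)

* **Exponential fits** are OLS on the log response (multiplicative error):
  closed-form, reproducible, and exact in the noiseless limit (refits
  recover coefficients to 1e−8 relative). A nonlinear-least-squares
  refinement (additive error) is available via `method="nls"` for
  sensitivity analysis.
* **Admissibility** is strict: a predictor set is admissible iff every
  internal pair has |r| < 0.69. The published trait matrix gives exactly 9
  admissible pairs (the boundary case plant-height–NDRE, r = 0.68, is
  admitted) and accepts the stated plant-height + cover + NDRE triple, for
  the 10 standard multi-predictor sets. On simulated data the screen is
  recomputed from the sample matrix; sets that happen to violate it there
  (e.g. NDVI+RGBVI, whose simulated correlation is high because both
  derive from the red band) are skipped with a logged reason rather than
  forced.
* **Validation** — seeded 4:1 train/test split (test = round(n/5), so 363
  samples split 290/73); 10-fold CV with seeded shuffled folds
  (`sklearn.model_selection.KFold`), reporting the mean and the n−1-
  denominator standard deviation of the fold RMSEs; test-set RMSE and
  Pearson r (two-sided p from the t transform, n−2 df). Constant
  predictions yield RMSE with a flagged-undefined r.
* **t-tests** are pooled-variance Student (Welch via `equal_var=False`);
  p-values are reported raw, without multiple-testing correction, matching
  standard practice for a handful of preplanned contrasts.

## Reproducibility

All randomness flows from one root seed through named substreams (design,
truths, render, shadows; `numpy` `SeedSequence([seed, stage])`), so each
stage is independently reproducible and a full scene is bit-identical for
identical (config, seed). Scene directories carry a SHA-256 manifest.

## Problem sizes

The analysis drivers and acceptance tests run the pipeline at the trial's
full size — 384 plots, ~9.1 M multispectral pixels, ~21.6 M surface-model
pixels — which completes in about a minute on one CPU. Unit and property
tests use reduced fields (1–16 plots) and the parameter-recovery studies
use 2000 plots x 20 replicates, chosen so the Monte-Carlo error on mean
coefficients (≲0.5 %) sits well inside the 2 % recovery tolerance.

## What passing tests do and do not show

The generator reproduces the *statistical and optical structure* the
analysis assumes: an RCBD layout, exponential trait-biomass links with
multiplicative noise, treatment-shifted chlorophyll indices, and shadows
with inflated NDVI and suppressed ExG. It does not attempt radiative-
transfer realism: canopies are flat-topped strips (no leaf geometry, no
panicles, no mutual illumination), spectra are five-point with independent
Gaussian noise (no sensor PSF, no mosaicking seams or nodata edges), the
ExG threshold separates classes by construction rather than by trial and
error, and within-plot height variation is uncorrelated jitter rather than
measured canopy texture. Passing tests therefore demonstrate that the
*pipeline* — segmentation, terrain interpolation, zonal statistics,
index algebra, fitting and validation — is correct and unbiased under the
stated generative model, not that the published field-data correlations
would be reproduced on new imagery. A single invocation renders one flight
date; multi-date studies are multiple invocations with different
height/cover parameters.

## Known limitations

* The DTM is row-wise linear east-west; fields with north-south terrain
  trends need denser soil sampling than two flanking strips.
* Shadow casting is binary (umbra only) with fixed attenuation factors; no
  penumbra, no diffuse-fraction dependence on sky condition.
* Canopy cover from sunlit pixels is biased low for plots substantially
  shaded by taller neighbours — a real effect of the method, visible in
  the simulator, and the reason cover tolerances are quantile-based.
* The continuous cover parameter is quantized by the raster grid when row
  strips are rendered (~0.01 at 2 cm GSD), so sub-pixel cover agreement is
  defined against the rendered vegetation fraction.
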