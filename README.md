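# canophen

Plot-level crop phenotyping from multiband aerial imagery, built around the
analysis of a 384-plot energy-sorghum nitrogen trial: shadow-aware
vegetation segmentation, extraction of plant height / canopy cover / eight
vegetation indices per plot, and exponential regression of fresh and dry
biomass on those traits, together with nitrogen-treatment t-tests and
VI-versus-leaf-chemistry correlations.

Because the raw field imagery behind such trials is rarely deposited, the
package ships a first-class synthetic scene generator that emulates the
study design end to end — a randomized complete block field (24 lines x 2
nitrogen treatments x 8 replicates, 3 m x 3 m plots with four crop rows at
0.76 m spacing), a 5-band reflectance orthomosaic (blue / green / red /
red-edge / NIR, 2 cm GSD, 16-bit DN with 32768 = 100 % reflectance), a
photogrammetric surface model (1.3 cm GSD), and geometric cast shadows that
reproduce a well-known field artifact: shaded pixels show *higher* NDVI
than sunlit canopy, while their excess green (ExG) collapses, so a single
ExG threshold removes both soil and shadow.

## The analysis in brief

1. **Segmentation.** ExG = 2ρ_G − ρ_R − ρ_B per pixel; pixels with
   ExG > 0.046 are sunlit vegetation. Soil and shaded pixels fall below the
   threshold; shaded pixels must be removed because differential
   atmospheric scattering under shadow inflates NIR-based indices.
2. **Morphological traits.** Plant height = (DSM − DTM) x 100 cm, the DTM
   linearly interpolated per raster row from bare-soil strips flanking the
   field east and west. Per plot, the 90/93/95/98th percentiles of all
   in-plot height pixels are candidates; the one correlating best with
   manual measurements is kept. Canopy cover = sunlit-vegetation pixels /
   all plot pixels.
3. **Spectral traits.** Eight indices (ExG, NDVI, RDVI, GNDVI, CI_green,
   CI_rededge, NDRE, RGBVI) averaged over each plot's sunlit-vegetation
   pixels. RDVI uses the renormalized form (ρ_NIR − ρ_R)/√(ρ_NIR + ρ_R).
4. **Modelling.** Simple and multiple exponential regressions
   Y = a·e^(Σ bⱼxⱼ), fitted by ordinary least squares on ln Y. Predictor
   sets are screened on the trait correlation matrix (every pair must have
   |r| < 0.69). Models are built on a seeded 4:1 train/test split,
   validated by 10-fold cross-validation (mean and spread of fold RMSEs),
   and evaluated on the test set by RMSE and Pearson r. Student's t-tests
   compare chlorophyll-sensitive VIs between nitrogen treatments, and
   plot-mean VIs are correlated with lab-measured leaf nitrogen and
   chlorophyll.

## Worked example

The one-shot demo simulates a reduced 16-plot field, extracts traits from
the rendered imagery, and refits the generative biomass model from them:

```sh
$ canophen demo --seed 2
simulating a 16-plot field (seed 2)
generating fresh-biomass model: Y = 21.22 x e^(0.005 x PH)
refitted from extracted traits:  Y = 20.88 x e^(0.005105 x PH)
coefficient recovery: |da|/a = 1.6%, |db|/b = 2.1%
mean |canopy-cover error| = 0.011, mean |height error| = 5.1 cm
```

The refit recovers the generating coefficients to ~2 % from 16 plots of
rendered imagery — the whole chain (rendering, shadow casting, ExG
segmentation, terrain interpolation, zonal statistics, log-linear fitting)
is exercised in one pass.

The full-scale analysis lives under `analysis/` as numbered drivers:

```sh
python analysis/01_simulate_trial_scene.py   # 384-plot scene -> scratch/scene
python analysis/02_extract_plot_traits.py    # traits + summary tables
python analysis/03_fit_biomass_models.py     # results/report/*.csv
python analysis/04_nitrogen_and_chlorophyll.py
python analysis/05_parameter_recovery.py     # results/parameter_recovery.csv
```

On the default scene these report 100 % segmentation agreement with the
simulator's pixel labels, mean plot-height error ~9.5 cm and cover error
~0.01, all three chlorophyll indices strongly separated by nitrogen
treatment (t between 8.9 and 17.3, p < 1e-16), and NDRE/CI_rededge
correlating with leaf nitrogen and chlorophyll at r ≈ 0.57.

The same stages are scriptable through the CLI
(`canophen simulate | segment | extract | model | demo`); see
`canophen --help`.

## Layout

```
src/canophen/      geo_io, scene_sim, segmentation, traits, models,
                   recovery, reference, pipeline, cli
analysis/          numbered narrative drivers (write under results/)
tests/             pytest suite incl. the acceptance tests
scripts/           acceptance.py
docs/methods.md    model, assumptions, parameter choices, limitations
```
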