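"""Plot traits: terrain interpolation, heights, cover, vegetation indices."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from canophen.geo_io import REDEDGE_BANDS, BandDefinition, GridGeometry, rasterize_plot
from canophen.segmentation import Mask, sunlit_vegetation_mask
from canophen.traits import (
    InterpolationError,
    canopy_cover,
    compute_vi,
    estimate_dtm,
    extract_scene_traits,
    height_map,
    plot_height_percentile,
    plot_mean_vi,
    select_height_percentile,
    resample_spectrum_to_bands,
)

from conftest import make_stack


def _grid(n_rows=20, n_cols=30, gsd=0.5):
    return GridGeometry(0.0, n_rows * gsd, gsd, gsd, n_rows, n_cols)


class TestEstimateDtm:
    def _strips(self, grid, width=2.0):
        minx, miny, maxx, maxy = grid.bounds()
        west = box(minx, miny, minx + width, maxy)
        east = box(maxx - width, miny, maxx, maxy)
        return west, east

    def test_flat_surface_recovered_exactly(self):
        grid = _grid()
        dsm = np.full(grid.shape, 100.0)
        dtm = estimate_dtm(dsm, grid, *self._strips(grid))
        np.testing.assert_allclose(dtm, 100.0)

    def test_linear_interpolation_between_strip_centers(self):
        grid = _grid(10, 100, 1.0)
        dsm = np.full(grid.shape, 100.0)
        dsm[:, 95:] = 102.0  # east strip higher
        west = box(0, 0, 5, 10)
        east = box(95, 0, 100, 10)
        dtm = estimate_dtm(dsm, grid, west, east)
        # strip centers at columns 2 and 97: midpoint column 49.5
        mid = 0.5 * (dtm[:, 49] + dtm[:, 50])
        np.testing.assert_allclose(mid, 101.0)
        np.testing.assert_allclose(dtm[:, 0], 100.0)   # constant extrapolation
        np.testing.assert_allclose(dtm[:, -1], 102.0)

    def test_shift_equivariance(self):
        grid = _grid()
        rng = np.random.default_rng(0)
        dsm = 100 + rng.normal(0, 0.05, grid.shape)
        w, e = self._strips(grid)
        np.testing.assert_allclose(
            estimate_dtm(dsm + 5.0, grid, w, e), estimate_dtm(dsm, grid, w, e) + 5.0
        )

    def test_empty_strip_row_raises_naming_the_row(self):
        grid = _grid(6, 30, 1.0)
        dsm = np.full(grid.shape, 50.0)
        west = box(0, 0, 2, 3)  # only covers the southern half of the rows
        east = box(28, 0, 30, 6)
        with pytest.raises(InterpolationError, match="row"):
            estimate_dtm(dsm, grid, west, east)


class TestHeightMap:
    def test_equal_surfaces_give_zero_height(self):
        dsm = np.full((4, 4), 101.0)
        np.testing.assert_array_equal(height_map(dsm, dsm), 0.0)

    def test_metres_convert_to_centimetres(self):
        dtm = np.full((2, 2), 100.0)
        np.testing.assert_allclose(height_map(dtm + 3.5, dtm), 350.0)

    def test_negative_differences_clip_to_zero(self):
        dtm = np.full((2, 2), 100.0)
        np.testing.assert_array_equal(height_map(dtm - 0.02, dtm), 0.0)


class TestPlotHeightPercentile:
    def test_constant_plot_at_every_percentile(self):
        h = np.full((10, 10), 200.0)
        px = (np.arange(100) // 10, np.arange(100) % 10)
        for q in (90, 93, 95, 98):
            assert plot_height_percentile(h, px, q) == 200.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6), st.integers(10, 2000),
           st.sampled_from([90, 93, 95, 98]))
    def test_matches_sort_and_interpolate_oracle(self, seed, n, q):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(0, 400, n)
        h = vals.reshape(1, -1)
        px = (np.zeros(n, dtype=int), np.arange(n))
        got = plot_height_percentile(h, px, q)
        # independent oracle: sorted order statistics, linear interpolation
        s = np.sort(vals)
        pos = (q / 100) * (n - 1)
        lo, hi = int(math.floor(pos)), int(math.ceil(pos))
        expected = s[lo] + (pos - lo) * (s[hi] - s[lo])
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        h = rng.uniform(0, 400, (50, 50))
        px = (np.repeat(np.arange(50), 50), np.tile(np.arange(50), 50))
        qs = [plot_height_percentile(h, px, q) for q in (90, 93, 95, 98)]
        assert qs == sorted(qs)

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(ValueError):
            plot_height_percentile(np.ones((2, 2)), (np.array([], int),) * 2, 90)


class TestCanopyCover:
    def test_extreme_masks(self):
        grid = _grid(10, 10, 1.0)
        px = (np.repeat(np.arange(10), 10), np.tile(np.arange(10), 10))
        ones = Mask(np.ones((10, 10), bool), grid)
        zeros = Mask(np.zeros((10, 10), bool), grid)
        assert canopy_cover(ones, px) == 1.0
        assert canopy_cover(zeros, px) == 0.0

    def test_half_sunlit_plot(self):
        grid = _grid(150, 150, 0.02)
        vals = np.zeros((150, 150), bool)
        vals[:75] = True
        px = rasterize_plot(box(0, 0, 3, 3), grid)
        assert len(px[0]) == 22500
        assert canopy_cover(Mask(vals, grid), px) == 0.5


class TestComputeVi:
    @pytest.mark.parametrize(
        "name,bands,expected",
        [
            ("ndvi", {"nir": 0.5, "red": 0.5}, 0.0),
            ("ndvi", {"nir": 0.8, "red": 0.2}, 0.6),
            ("ci_rededge", {"nir": 0.6, "red_edge": 0.3}, 1.0),
            ("ci_green", {"nir": 0.6, "green": 0.2}, 2.0),
            ("rgbvi", {"green": 0.2, "blue": 0.1, "red": 0.4}, 0.0),
            ("rdvi", {"nir": 0.8, "red": 0.2}, 0.6),  # 0.6 / sqrt(1.0)
            ("ndre", {"nir": 0.6, "red_edge": 0.2}, 0.5),
            ("gndvi", {"nir": 0.6, "green": 0.2}, 0.5),
        ],
    )
    def test_hand_computed_values(self, name, bands, expected):
        defaults = {"blue": 0.1, "green": 0.1, "red": 0.1, "red_edge": 0.1, "nir": 0.1}
        stack = make_stack({**defaults, **bands})
        np.testing.assert_allclose(compute_vi(stack, name), expected, atol=1e-12)

    def test_rdvi_canonical_form_divides_by_square_root(self):
        stack = make_stack({"blue": 0.1, "green": 0.1, "red": 0.1,
                            "red_edge": 0.3, "nir": 0.7})
        np.testing.assert_allclose(compute_vi(stack, "rdvi"),
                                   0.6 / math.sqrt(0.8), atol=1e-12)
        np.testing.assert_allclose(compute_vi(stack, "rdvi", printed_variant=True),
                                   0.6 / 0.8, atol=1e-12)

    def test_unknown_index_rejected(self):
        stack = make_stack({n: 0.2 for n in ("blue", "green", "red", "red_edge", "nir")})
        with pytest.raises(ValueError, match="unknown"):
            compute_vi(stack, "evi")

    def test_division_by_zero_yields_nodata(self):
        stack = make_stack({"blue": 0.0, "green": 0.0, "red": 0.0,
                            "red_edge": 0.0, "nir": 0.0})
        assert np.isnan(compute_vi(stack, "ndvi")).all()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_normalized_indices_bounded_and_scale_invariant(self, seed):
        rng = np.random.default_rng(seed)
        vals = {n: rng.uniform(0.01, 1.5, (4, 4)) for n in
                ("blue", "green", "red", "red_edge", "nir")}
        stack = make_stack(vals)
        c = rng.uniform(0.5, 3.0)
        scaled = make_stack({n: v * c for n, v in vals.items()})
        for name in ("ndvi", "gndvi", "ndre", "rgbvi"):
            vi = compute_vi(stack, name)
            assert np.all(np.abs(vi) <= 1 + 1e-12)
            np.testing.assert_allclose(compute_vi(scaled, name), vi, atol=1e-9)
        for name in ("ci_green", "ci_rededge"):
            vi = compute_vi(stack, name)
            assert np.all(vi >= -1)
            np.testing.assert_allclose(compute_vi(scaled, name), vi, atol=1e-9)


class TestPlotMeanVi:
    def test_constant_raster(self):
        grid = _grid(4, 4, 1.0)
        vi = np.full((4, 4), 0.7)
        mask = Mask(np.ones((4, 4), bool), grid)
        px = (np.repeat(np.arange(4), 4), np.tile(np.arange(4), 4))
        assert plot_mean_vi(vi, mask, px) == pytest.approx(0.7)

    def test_masked_out_pixels_excluded(self):
        grid = _grid(1, 2, 1.0)
        vi = np.array([[0.2, 0.9]])
        mask = Mask(np.array([[True, False]]), grid)
        px = (np.array([0, 0]), np.array([0, 1]))
        assert plot_mean_vi(vi, mask, px) == pytest.approx(0.2)

    def test_zero_sunlit_pixels_flags_missing_not_raises(self):
        grid = _grid(2, 2, 1.0)
        mask = Mask(np.zeros((2, 2), bool), grid)
        px = (np.array([0]), np.array([0]))
        assert math.isnan(plot_mean_vi(np.ones((2, 2)), mask, px))

    def test_sunlit_only_mean_not_above_all_pixel_mean_under_shadow(self, small_scene):
        """Shadow inflation: restricting to sunlit pixels lowers plot NDVI."""
        ndvi = compute_vi(small_scene.bands, "ndvi")
        mask = sunlit_vegetation_mask(small_scene.bands, 0.046)
        veg_any = Mask(
            np.isin(small_scene.labels, [2, 3]), small_scene.bands.grid
        )
        worse = 0
        for rec in small_scene.plots:
            px = rasterize_plot(rec.polygon, small_scene.bands.grid)
            sunlit = plot_mean_vi(ndvi, mask, px)
            allveg = plot_mean_vi(ndvi, veg_any, px)
            if sunlit <= allveg + 1e-9:
                worse += 1
        assert worse == len(small_scene.plots)


class TestExtractSceneTraits:
    def test_one_row_per_plot_with_expected_columns(self, small_scene,
                                                    small_scene_traits):
        t = small_scene_traits
        assert len(t) == len(small_scene.plots)
        for col in ("plot_id", "ph90", "ph93", "ph95", "ph98", "cc", "exg", "ndvi",
                    "rdvi", "gndvi", "ci_green", "ci_rededge", "ndre", "rgbvi",
                    "n_pixels", "n_sunlit"):
            assert col in t.columns
        assert t["valid"].all()
        np.testing.assert_allclose(t["cc"], t["n_sunlit"] / t["n_pixels"])

    def test_height_and_cover_recovered_on_default_scene(self, small_scene,
                                                         small_scene_traits):
        m = small_scene_traits.merge(small_scene.truth, on="plot_id")
        ph_ok = (np.abs(m["ph90"] - m["true_height_cm"]) / m["true_height_cm"]
                 <= 0.10).mean()
        cc_ok = (np.abs(m["cc"] - m["true_cover"]) <= 0.05).mean()
        assert ph_ok >= 0.90
        assert cc_ok >= 0.90

    def test_noiseless_scene_recovers_traits_near_exactly(self, noiseless_scene):
        t = extract_scene_traits(noiseless_scene)
        m = t.merge(noiseless_scene.truth, on="plot_id")
        assert np.abs(m["ph90"] - m["true_height_cm"]).max() < 1.0      # < 1 cm
        # cover to within one pixel of the rendered vegetation fraction
        # (the continuous cover parameter itself is quantized by the grid)
        veg = np.isin(noiseless_scene.labels, [2, 3])
        for _, row in m.iterrows():
            rec = noiseless_scene.plots[row["plot_id"]]
            rr, cc = rasterize_plot(rec.polygon, noiseless_scene.bands.grid)
            rendered = float(veg[rr, cc].mean())
            assert abs(row["cc"] - rendered) <= 1.0 / row["n_pixels"] + 1e-12
            assert abs(row["cc"] - row["true_cover"]) <= 0.05
        np.testing.assert_allclose(m["ndvi"], m["ndvi_latent"], atol=1e-6)
        np.testing.assert_allclose(m["ndre"], m["ndre_latent"], atol=1e-6)


class TestSelectHeightPercentile:
    def _traits(self):
        rng = np.random.default_rng(0)
        n = 40
        base = rng.uniform(100, 400, n)
        return pd.DataFrame(
            {"plot_id": [f"P{i:03d}" for i in range(n)],
             "ph90": base, "ph93": base * 1.01 + rng.normal(0, 5, n),
             "ph95": base * 1.02 + rng.normal(0, 5, n),
             "ph98": base * 1.03 + rng.normal(0, 5, n)}
        )

    def test_exact_match_returns_that_percentile_with_r_one(self):
        t = self._traits()
        measured = pd.Series(t["ph90"].to_numpy(), index=t["plot_id"])
        q, table = select_height_percentile(t, measured)
        assert q == 90
        assert table[90] == pytest.approx(1.0)

    def test_noisy_match_prefers_the_generating_percentile(self):
        t = self._traits()
        rng = np.random.default_rng(1)
        measured = pd.Series(
            t["ph95"].to_numpy() + rng.normal(0, 1.0, len(t)), index=t["plot_id"]
        )
        q, _ = select_height_percentile(t, measured)
        assert q == 95

    def test_ties_break_toward_lower_percentile(self):
        n = 10
        base = np.linspace(100, 400, n)
        t = pd.DataFrame({"plot_id": [f"P{i}" for i in range(n)],
                          **{f"ph{q}": base for q in (90, 93, 95, 98)}})
        measured = pd.Series(base * 2 + 5, index=t["plot_id"])
        q, table = select_height_percentile(t, measured)
        assert q == 90
        assert all(table[q] == pytest.approx(1.0) for q in (90, 93, 95, 98))

    def test_constant_measurement_rejected(self):
        t = self._traits()
        measured = pd.Series(200.0, index=t["plot_id"])
        with pytest.raises(ValueError):
            select_height_percentile(t, measured)


class TestResampleSpectrum:
    def test_flat_spectrum_passes_through(self):
        wl = np.arange(350, 2501, 1.0)
        out = resample_spectrum_to_bands(wl, np.full_like(wl, 0.5), REDEDGE_BANDS)
        assert set(out) == {"blue", "green", "red", "red_edge", "nir"}
        for v in out.values():
            assert v == pytest.approx(0.5, abs=1e-12)

    def test_linear_spectrum_evaluates_at_band_center(self):
        wl = np.arange(350, 2501, 1.0)
        refl = 1e-4 * wl
        out = resample_spectrum_to_bands(wl, refl, REDEDGE_BANDS)
        for band in REDEDGE_BANDS:
            assert out[band.name] == pytest.approx(1e-4 * band.center_nm, abs=1e-6)

    def test_step_spectrum_matches_fine_quadrature_oracle(self):
        wl = np.arange(350, 2501, 1.0)
        refl = np.where(wl < 700, 0.1, 0.6)
        band = BandDefinition("red", 668.0, 10.0)
        got = resample_spectrum_to_bands(wl, refl, [band])["red"]
        # oracle: direct numerical integration on a 0.1 nm grid
        fine = np.arange(band.center_nm - 1.5 * band.fwhm_nm,
                         band.center_nm + 1.5 * band.fwhm_nm + 1e-9, 0.1)
        r = np.where(fine < 700, 0.1, 0.6)
        sigma = band.fwhm_nm / (2 * math.sqrt(2 * math.log(2)))
        w = np.exp(-0.5 * ((fine - band.center_nm) / sigma) ** 2)
        expected = float(np.trapezoid(r * w, fine) / np.trapezoid(w, fine))
        assert got == pytest.approx(expected, abs=1e-4)

    def test_uncovered_band_support_rejected(self):
        wl = np.arange(500, 800, 1.0)
        with pytest.raises(ValueError, match="cover|gap"):
            resample_spectrum_to_bands(wl, np.full_like(wl, 0.5), REDEDGE_BANDS)
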