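"""Linearity, local linearity, SNR, low-contrast and MTF analyzers."""

import numpy as np
import pytest

import epidqc as e
from epidqc.errors import AnalysisError, SaturationError
from epidqc.metrics import (linearity, local_linearity, low_contrast, mtf,
                            snr)
from epidqc.simulate import PortalImage
from conftest import make_step_image


def hand_ols(x, y):
    """Closed-form least squares, independent of the implementation path."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestLinearity:
    def test_noise_free_render_is_linear(self, result_ideal):
        assert result_ideal.linearity.max_deviation < 0.1

    def test_interpolated_point_is_midpoint(self, rois_nominal, layout):
        values = {s.id: 3000.0 * (1 - s.attenuation_fraction)
                  for s in layout.copper_steps}
        values["cu_40"], values["cu_50"] = 400.0, 300.0
        img = make_step_image(rois_nominal, values)
        res = linearity(img, rois_nominal, layout)
        i45 = res.step_absorptions.index(0.45)
        assert res.step_means[i45] == pytest.approx(350.0)

    def test_injected_bump_is_localized_and_matches_hand_ols(self,
                                                             rois_nominal,
                                                             layout):
        values = {s.id: 3000.0 * (1 - s.attenuation_fraction)
                  for s in layout.copper_steps}
        values["cu_20"] *= 1.05            # +5 % bump on the 20 % step
        img = make_step_image(rois_nominal, values)
        res = linearity(img, rois_nominal, layout)
        assert res.worst_absorption == pytest.approx(0.20)
        x = np.asarray(res.step_absorptions)
        y = np.asarray(res.step_means)
        slope, intercept = hand_ols(x, y)
        dev = np.abs(y - (slope * x + intercept))
        expected = dev.max() / (abs(slope) * (x.max() - x.min())) * 100.0
        assert res.max_deviation == pytest.approx(expected, rel=1e-9)
        assert res.slope == pytest.approx(slope, rel=1e-9)

    def test_saturated_step_raises(self, rois_nominal, layout, image_ideal):
        px = np.array(image_ideal.pixels, copy=True)
        r0, c0, r1, c1 = rois_nominal["cu_00"].pixel_bounds
        px[r0:r1, c0:c1] = 65535.0
        img = PortalImage(pixels=px, imager=image_ideal.imager)
        with pytest.raises(SaturationError):
            linearity(img, rois_nominal, layout)

    def test_invariant_under_affine_gray_transform(self, image_blur, layout,
                                                   geometry):
        fit = e.calibrate(image_blur, layout, geometry)
        rois = e.locate_elements(fit, layout, e.ELEKTA)
        res1 = linearity(image_blur, rois, layout)
        scaled = PortalImage(pixels=1.7 * image_blur.pixels + 200.0,
                             imager=image_blur.imager)
        res2 = linearity(scaled, rois, layout)
        assert res2.max_deviation == pytest.approx(res1.max_deviation,
                                                   rel=1e-9)
        loc1 = local_linearity(image_blur, rois, layout)
        loc2 = local_linearity(scaled, rois, layout)
        assert loc2.worst_deviation == pytest.approx(loc1.worst_deviation,
                                                     rel=1e-9)


class TestLocalLinearity:
    def test_noise_free_blocks_are_linear(self, result_ideal):
        assert result_ideal.local_linearity.worst_deviation < 0.1
        assert len(result_ideal.local_linearity.per_block) == 6

    def test_quadratic_distortion_flags_the_block(self, rois_nominal, layout):
        values = {}
        for name, steps in layout.brass_blocks.items():
            for s in steps:
                v = 3000.0 * (1 - s.attenuation_fraction)
                if name == "brass_q3a":    # quadratic gain distortion
                    v += 800.0 * s.attenuation_fraction ** 2
                values[s.id] = v
        img = make_step_image(rois_nominal, values)
        res = local_linearity(img, rois_nominal, layout)
        assert res.worst_block == "brass_q3a"
        x = [s.attenuation_fraction for s in layout.brass_blocks["brass_q3a"]]
        y = [values[s.id] for s in layout.brass_blocks["brass_q3a"]]
        slope, intercept = hand_ols(x, y)
        dev = np.abs(np.asarray(y) - (slope * np.asarray(x) + intercept))
        expected = dev.max() / (abs(slope) * (max(x) - min(x))) * 100.0
        assert res.worst_deviation == pytest.approx(expected, rel=1e-9)
        others = [v for k, v in res.per_block.items() if k != "brass_q3a"]
        assert all(v < 1e-6 for v in others)

    def test_missing_steps_raise(self, image_ideal, rois_nominal, layout):
        rois = dict(rois_nominal)
        del rois["brass_ne_10"]
        with pytest.raises(AnalysisError):
            local_linearity(image_ideal, rois, layout)


class TestSNR:
    def test_moment_recovery_on_uniform_noise(self, rois_nominal, layout):
        c, sigma = 2400.0, 40.0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = PortalImage(
                pixels=c + rng.normal(0, sigma, (1024, 1024)), imager=e.ELEKTA)
            res = snr(img, rois_nominal, layout)
            assert res.mean_snr == pytest.approx(c / sigma ** 2, rel=0.05)
            res_std = snr(img, rois_nominal, layout, convention="std")
            assert res_std.mean_snr == pytest.approx(c / sigma, rel=0.05)

    def test_variance_estimator_bias_below_one_percent(self):
        sigma = 25.0
        rng = np.random.default_rng(42)
        estimates = [rng.normal(0, sigma, 10000).var() for _ in range(200)]
        assert abs(np.mean(estimates) - sigma ** 2) / sigma ** 2 < 0.01

    def test_noise_free_flags_infinite(self, image_ideal, rois_nominal, layout):
        res = snr(image_ideal, rois_nominal, layout)
        assert res.infinite
        assert np.isinf(res.mean_snr)
        assert len(res.per_step_snr) == 10

    def test_mean_snr_nondecreasing_with_mu(self, layout, geometry):
        values = []
        for mu in (1.0, 2.0, 5.0):
            truth = e.SyntheticTruth(
                mu=mu, noise=e.NoiseModel(read_sigma=30.0, gain=1.0, seed=11))
            img = e.render(layout, geometry, e.ELEKTA, truth)
            fit = e.calibrate(img, layout, geometry)
            rois = e.locate_elements(fit, layout, e.ELEKTA)
            values.append(snr(img, rois, layout).mean_snr)
        assert values[0] <= values[1] <= values[2]
        # moment model: per-step SNR = c / (read^2 + gain*c), c = signal
        c = 3000.0 * np.mean([1 - s.attenuation_fraction
                              for s in layout.copper_steps])
        assert values[0] == pytest.approx(c / (900.0 + c), rel=0.1)

    def test_unknown_convention_rejected(self, image_ideal, rois_nominal,
                                         layout):
        with pytest.raises(ValueError):
            snr(image_ideal, rois_nominal, layout, convention="rms")


class TestLowContrast:
    def test_grid_structure_and_column_uniformity(self, image_ideal, nominal,
                                                  layout):
        res = low_contrast(image_ideal, nominal, layout)
        assert res.populated == 27
        assert res.grid.shape == (5, 6)
        for i, j in ((0, 0), (0, 1), (0, 2)):       # vacant cells
            assert np.isnan(res.grid[i, j])
        # columns share a depth: noise-free contrast equal within a column
        for j in range(6):
            col = res.grid[:, j]
            col = col[np.isfinite(col)]
            assert col.std() / col.mean() < 0.02
        # contrast proportional to the column's depth attenuation
        depths = np.asarray(e.phantom.HOLE_DEPTHS)
        col_means = np.nanmean(res.grid, axis=0)
        ratio = col_means / (3000.0 * 0.01 * depths)
        assert np.all(np.abs(ratio - 1.0) < 0.05)

    def test_deepest_largest_hole_has_max_contrast(self, image_ideal, nominal,
                                                   layout):
        res = low_contrast(image_ideal, nominal, layout)
        # noise-free contrast is set by depth alone, so the deepest column
        # ties across diameters; the deepest & largest hole attains the max
        assert res.grid[4, 5] == pytest.approx(np.nanmax(res.grid), rel=1e-4)
        assert bool(res.detectable[4, 5])

    def test_noise_free_all_detectable(self, image_ideal, nominal, layout):
        res = low_contrast(image_ideal, nominal, layout)
        assert int(res.detectable.sum()) == 27

    def test_shallow_small_holes_drop_first_under_noise(self, image_noisy,
                                                        layout, geometry):
        fit = e.calibrate(image_noisy, layout, geometry)
        res = low_contrast(image_noisy, fit, layout)
        assert bool(res.detectable[4, 5])          # deepest & largest
        assert not bool(res.detectable[1, 0])      # shallowest & near-smallest

    def test_relative_grid_is_exposure_free(self, image_ideal, nominal,
                                            layout):
        res = low_contrast(image_ideal, nominal, layout)
        scaled = PortalImage(pixels=7.0 * np.asarray(image_ideal.pixels),
                             imager=image_ideal.imager)
        res7 = low_contrast(scaled, nominal, layout)
        np.testing.assert_allclose(res7.grid_relative, res.grid_relative,
                                   rtol=1e-9)
        np.testing.assert_allclose(res7.grid, 7.0 * res.grid, rtol=1e-9)


class TestMTF:
    def test_delta_psf_normalized_near_unity(self, result_ideal):
        for o in (result_ideal.mtf.in_plane, result_ideal.mtf.cross_plane):
            for f, n, ok in zip(o.frequencies, o.normalized, o.valid):
                if ok and f <= 1.0:        # half-period >= 2 px
                    assert abs(n - 1.0) <= 0.02

    def test_normalization_anchor_is_exactly_one(self, image_blur, layout,
                                                 geometry):
        fit = e.calibrate(image_blur, layout, geometry)
        res = mtf(image_blur, fit, layout)
        for o in (res.in_plane, res.cross_plane):
            first = next(i for i, ok in enumerate(o.valid) if ok)
            assert o.normalized[first] == 1.0
            assert o.frequencies[first] == pytest.approx(0.167)

    def test_gaussian_blur_monotone_decreasing(self, image_blur, layout,
                                               geometry):
        fit = e.calibrate(image_blur, layout, geometry)
        res = mtf(image_blur, fit, layout)
        for o in (res.in_plane, res.cross_plane):
            vals = [n for n, ok in zip(o.normalized, o.valid) if ok]
            assert all(b <= a + 0.02 for a, b in zip(vals, vals[1:]))

    def test_fine_stripes_flagged_invalid_not_fatal(self, result_ideal):
        o = result_ideal.mtf.in_plane
        for f, ok in zip(o.frequencies, o.valid):
            if f > 1.34:                   # stripe width < 1.5 px at 4 px/mm
                assert not ok
        assert any(o.valid)

    def test_above_nyquist_flagged(self, result_ideal):
        for o in (result_ideal.mtf.in_plane, result_ideal.mtf.cross_plane):
            for f, above in zip(o.frequencies, o.above_nyquist):
                assert above == (f > 2.0)  # 4 px/mm in the phantom plane

    def test_stripe_mean_method_agrees_at_low_frequency(self, image_blur,
                                                        layout, geometry):
        fit = e.calibrate(image_blur, layout, geometry)
        res_fit = mtf(image_blur, fit, layout)
        res_sm = mtf(image_blur, fit, layout, method="stripe_mean")
        for o_f, o_s in ((res_fit.in_plane, res_sm.in_plane),
                         (res_fit.cross_plane, res_sm.cross_plane)):
            first = next(i for i, ok in enumerate(o_s.valid) if ok)
            assert o_s.normalized[first] == 1.0
            # stripe means read at or below the peak contrast
            for rf, rs, ok in zip(o_f.raw_contrast, o_s.raw_contrast, o_s.valid):
                if ok:
                    assert rs <= rf + 0.02
        assert res_sm.method == "stripe_mean"

    def test_mtf50_not_reached_reports_last_valid(self, result_ideal):
        o = result_ideal.mtf.in_plane      # delta PSF: no 0.5 crossing
        assert not o.mtf50_reached and o.mtf50 is None
        assert o.last_valid_frequency == pytest.approx(1.0, abs=0.01)

    def test_unknown_method_rejected(self, image_ideal, nominal, layout):
        with pytest.raises(ValueError):
            mtf(image_ideal, nominal, layout, method="slanted_edge")


class TestCSVExport:
    def test_mtf_and_grid_csv(self, result_ideal):
        from epidqc.metrics import low_contrast_to_csv, mtf_to_csv
        csv = mtf_to_csv(result_ideal.mtf)
        rows = csv.strip().splitlines()
        assert rows[0].startswith("orientation,frequency")
        assert len(rows) == 1 + 12 + 12      # 12 frequencies per orientation
        grid = low_contrast_to_csv(result_ideal.low_contrast).strip().splitlines()
        assert len(grid) == 6                # header + 5 diameter rows
        assert grid[1].split(",")[1] == ""   # vacant cell stays empty


class TestQAResult:
    def test_summary_and_json_round_trip(self, result_ideal):
        import json
        s = result_ideal.summary()
        assert set(s) == {"rotation_deg", "calibration_residual_px",
                          "linearity_max_deviation_pct",
                          "local_linearity_worst_pct", "mean_snr",
                          "mtf50_in_plane", "mtf50_cross_plane"}
        data = json.loads(result_ideal.to_json())
        assert data["polarity"] == "attenuation_dark"
        assert data["summary"]["mean_snr"] is None    # noise-free: infinite
        assert len(data["linearity"]["step_means"]) == 11
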