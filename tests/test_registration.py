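"""Corner refinement, similarity calibration, ROI localization, polarity."""

import numpy as np
import pytest

import epidqc as e
from epidqc.errors import DetectionError, FitError, PolarityError
from epidqc.registration import (CalibrationTransform, detect_polarity,
                                 fit_calibration, locate_elements,
                                 refine_corner)
from epidqc.simulate import PortalImage, _forward


def marker_window(center=(30.3, 28.7), half=8.0, bg=3000.0, contrast=0.45,
                  size=61, noise=0.0, seed=0):
    """Small image holding one dark square marker with sub-pixel edges
    (analytic pixel-coverage rasterization)."""
    rr, cc = np.mgrid[0:size, 0:size].astype(float)

    def cov(d):
        lo = np.maximum(d - 0.5, -half)
        hi = np.minimum(d + 0.5, half)
        return np.clip(hi - lo, 0.0, 1.0)

    frac = cov(rr - center[0]) * cov(cc - center[1])
    px = bg * (1.0 - contrast * frac)
    if noise > 0:
        rng = np.random.default_rng(seed)
        px = px + rng.normal(0.0, noise, px.shape)
    imager = e.ImagerSpec("win", (size, size), 0.4,
                          (size * 0.04, size * 0.04), 160.0)
    return PortalImage(pixels=np.clip(px, 0, None), imager=imager)


class TestRefineCorner:
    def test_noise_free_centroid_subpixel(self):
        img = marker_window()
        r, c = refine_corner(img, (30, 30), window=61)
        assert abs(r - 30.3) < 0.1 and abs(c - 28.7) < 0.1

    def test_centroid_under_two_percent_noise(self):
        errs = []
        for seed in range(100):
            img = marker_window(noise=60.0, seed=seed)
            r, c = refine_corner(img, (30, 30), window=61)
            errs.append(np.hypot(r - 30.3, c - 28.7))
        assert max(errs) < 0.5

    def test_flat_window_raises(self):
        imager = e.ImagerSpec("win", (61, 61), 0.4, (2.44, 2.44), 160.0)
        img = PortalImage(pixels=np.full((61, 61), 3000.0), imager=imager)
        with pytest.raises(DetectionError):
            refine_corner(img, (30, 30), window=61)

    def test_pure_noise_window_raises(self):
        rng = np.random.default_rng(5)
        imager = e.ImagerSpec("win", (61, 61), 0.4, (2.44, 2.44), 160.0)
        img = PortalImage(pixels=3000 + rng.normal(0, 40, (61, 61)).clip(-2999),
                          imager=imager)
        with pytest.raises(DetectionError):
            refine_corner(img, (30, 30), window=61)

    def test_marker_found_on_rendered_image(self, image_ideal, layout, nominal):
        for mk in layout.corner_markers:
            truth_px = nominal.to_pixels(*mk.center)
            found = refine_corner(image_ideal, truth_px, window=141)
            assert np.hypot(found[0] - truth_px[0],
                            found[1] - truth_px[1]) < 0.1


class TestFitCalibration:
    MODEL = [(112.0, 112.0), (-112.0, 112.0), (-112.0, -112.0), (112.0, -112.0)]

    def _detected(self, rotation=0.0, translation=(511.5, 511.5), scale=4.0):
        t = CalibrationTransform(scale=scale, rotation_deg=rotation,
                                 translation=translation)
        return [t.to_pixels(x, y) for x, y in self.MODEL]

    def test_identity_recovery(self):
        fit = fit_calibration(self._detected(), self.MODEL)
        assert abs(fit.rotation_deg) < 1e-6
        assert fit.scale == pytest.approx(4.0)
        assert fit.residual < 1e-9

    def test_rotation_recovery_exact_points(self):
        fit = fit_calibration(self._detected(rotation=2.0), self.MODEL)
        assert fit.rotation_deg == pytest.approx(2.0, abs=1e-9)

    def test_perturbed_corner_inflates_residual(self):
        det = self._detected()
        det[2] = (det[2][0] + 5.0, det[2][1])
        fit = fit_calibration(det, self.MODEL)
        assert fit.residual > 1.0

    def test_collinear_points_rejected(self):
        model = [(0, 0), (10, 10), (20, 20), (30, 30)]
        det = [(100, 100), (110, 110), (120, 120), (130, 130)]
        with pytest.raises(FitError):
            fit_calibration(det, model)

    def test_rendered_recovery_with_misalignment(self, rotation_renders,
                                                 layout, geometry, nominal):
        for rot, (truth, img) in rotation_renders.items():
            fit = e.calibrate(img, layout, geometry)
            assert fit.rotation_deg == pytest.approx(rot, abs=0.05)
            # translation: position of the (misaligned) phantom origin
            want = nominal.to_pixels(*_forward(truth, 0.0, 0.0))
            got = fit.translation
            assert np.hypot(got[0] - want[0], got[1] - want[1]) < 0.2

    def test_manual_corner_seeds(self, image_ideal, layout, geometry, nominal):
        seeds = [nominal.to_pixels(*mk.center) for mk in layout.corner_markers]
        seeds = [(r + 6, c - 4) for r, c in seeds]    # sloppy manual clicks
        fit = e.calibrate(image_ideal, layout, geometry, corner_seeds=seeds)
        assert abs(fit.rotation_deg) < 0.05


class TestLocateElements:
    def test_roi_centers_match_projection(self, nominal, layout):
        rois = locate_elements(nominal, layout, e.ELEKTA)
        for el in layout.elements:
            want = nominal.to_pixels(*el.center)
            r0, c0, r1, c1 = rois[el.id].pixel_bounds
            assert abs((r0 + r1) / 2 - want[0]) <= 0.5
            assert abs((c0 + c1) / 2 - want[1]) <= 0.5

    def test_copper_rois_disjoint_in_pixels(self, rois_nominal, layout):
        boxes = [rois_nominal[s.id].pixel_bounds for s in layout.copper_steps]
        for i, a in enumerate(boxes):
            for b in boxes[i + 1:]:
                assert a[3] <= b[1] or b[3] <= a[1] or a[2] <= b[0] or b[2] <= a[0]

    def test_rotated_roi_contains_marker_centroid(self, rotation_renders,
                                                  layout, geometry):
        truth, img = rotation_renders[3.0]
        fit = e.calibrate(img, layout, geometry)
        rois = locate_elements(fit, layout, e.ELEKTA)
        for mk in layout.corner_markers:
            seed = fit.to_pixels(*mk.center)
            found = refine_corner(img, seed, window=101)
            r0, c0, r1, c1 = rois[mk.id].pixel_bounds
            assert r0 <= found[0] <= r1 and c0 <= found[1] <= c1

    def test_full_chain_recovers_centers_under_noise(self, image_noisy,
                                                     layout, geometry, nominal):
        fit = e.calibrate(image_noisy, layout, geometry)
        rois = locate_elements(fit, layout, e.ELEKTA)
        for el in layout.elements:
            want = nominal.to_pixels(*el.center)   # truth is unrotated
            r0, c0, r1, c1 = rois[el.id].pixel_bounds
            assert np.hypot((r0 + r1) / 2 - want[0],
                            (c0 + c1) / 2 - want[1]) < 1.0


class TestPolarity:
    def test_normal_image_detected_dark(self, image_ideal, rois_nominal):
        assert detect_polarity(image_ideal, rois_nominal) == "attenuation_dark"

    def test_inverted_image_detected_bright(self, image_ideal, rois_nominal,
                                            layout):
        inv = e.invert_polarity(image_ideal)
        assert detect_polarity(inv, rois_nominal) == "attenuation_bright"
        # after normalization the linearity slope matches the normal image
        norm, _ = e.registration.normalize_polarity(inv, rois_nominal)
        lin_inv = e.linearity(norm, rois_nominal, layout)
        lin = e.linearity(image_ideal, rois_nominal, layout)
        assert lin_inv.slope == pytest.approx(lin.slope, rel=1e-9)

    def test_uniform_image_is_indeterminate(self, rois_nominal):
        img = PortalImage(pixels=np.full((1024, 1024), 1000.0), imager=e.ELEKTA)
        with pytest.raises(PolarityError):
            detect_polarity(img, rois_nominal)
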