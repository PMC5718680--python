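"""Phantom registration: corner calibration, rotation, ROI localization.

The phantom position on the image is calibrated from the four corner
markers: each marker is refined to a sub-pixel centroid inside a search
window, a least-squares similarity transform (uniform scale + rotation +
translation) is fitted between the four model corners (phantom mm) and the
four detected corners (pixels), and every other test element is then mapped
to pixel bounds through that transform.  Gray-scale polarity (some imagers
export inverted gray scales) is detected by comparing the 0 % and 50 %
copper steps.

The classical workflow seeds the corner search manually (clicking the four
corner elements); here the seeds default to the nominal projection of the
layout so fully automatic operation is possible, and a second refinement
pass re-seeds from the first fit to tolerate misalignments larger than the
search window margin.

Transform convention: phantom (x, y) mm map to image "xy" coordinates
(col, -row) through ``p_img = scale * R(rotation) p + t``; rotation is
reported in degrees, positive counter-clockwise in the image (row 0 at the
top).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import SimilarityTransform

from . import phantom as ph
from .errors import CoverageError, DetectionError, FitError, PolarityError
from .simulate import MAX_GRAY, PortalImage, invert_polarity

__all__ = [
    "CalibrationTransform",
    "ElementROI",
    "refine_corner",
    "fit_calibration",
    "nominal_transform",
    "calibrate",
    "locate_elements",
    "roi_mean",
    "detect_polarity",
    "normalize_polarity",
]


@dataclass(frozen=True)
class CalibrationTransform:
    """Similarity transform from the phantom plane to pixel coordinates."""

    scale: float                      # pixels / mm
    rotation_deg: float               # CCW in the image, degrees
    translation: tuple[float, float]  # (row, col) pixel position of phantom origin
    residual: float = 0.0             # RMS over the calibration corners, pixels

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.residual < 0:
            raise ValueError("residual must be non-negative")

    def to_pixels(self, x, y):
        """Phantom (x, y) mm -> fractional (row, col)."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        row0, col0 = self.translation
        col = col0 + self.scale * (c * np.asarray(x) - s * np.asarray(y))
        row = row0 - self.scale * (s * np.asarray(x) + c * np.asarray(y))
        return (row, col)

    def to_phantom(self, row, col):
        """Fractional (row, col) -> phantom (x, y) mm."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        row0, col0 = self.translation
        u = (np.asarray(col) - col0) / self.scale
        v = (row0 - np.asarray(row)) / self.scale
        return (c * u + s * v, -s * u + c * v)


@dataclass(frozen=True)
class ElementROI:
    """Pixel-space region of one test element.

    ``pixel_bounds`` is the half-open outer bounding box (row0, col0, row1,
    col1) of the projected element; ``interior_margin`` is the symmetric
    shrink (pixels) that guarantees the shrunk box lies inside the element
    even under the fitted rotation, with at least a 10 % margin per side.
    """

    element_id: str
    pixel_bounds: tuple[int, int, int, int]
    interior_margin: int = 0

    def interior(self) -> tuple[int, int, int, int]:
        r0, c0, r1, c1 = self.pixel_bounds
        m = self.interior_margin
        return (r0 + m, c0 + m, r1 - m, c1 - m)

    def interior_slices(self) -> tuple[slice, slice]:
        r0, c0, r1, c1 = self.interior()
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"ROI {self.element_id} has empty interior")
        return (slice(r0, r1), slice(c0, c1))


# --------------------------------------------------------------------------
# corner refinement
# --------------------------------------------------------------------------

def refine_corner(image: PortalImage, approx, window: int = 141):
    """Sub-pixel centroid of the corner-marker blob near ``approx`` (row, col).

    The window background is estimated from the window border, the marker
    blob is segmented by Otsu thresholding of |gray - background| (which is
    polarity-agnostic), and the connected component closest to the window
    center is reduced to its intensity-weighted centroid.

    Raises :class:`DetectionError` when the window holds no blob.
    """
    px = np.asarray(image.pixels, dtype=float)
    half = window // 2
    r, c = int(round(approx[0])), int(round(approx[1]))
    r0, r1 = max(0, r - half), min(px.shape[0], r + half + 1)
    c0, c1 = max(0, c - half), min(px.shape[1], c + half + 1)
    win = px[r0:r1, c0:c1]
    if win.size < 9:
        raise DetectionError("search window falls outside the image")

    border = np.concatenate([win[0, :], win[-1, :], win[:, 0], win[:, -1]])
    bg = float(np.median(border))
    dev = np.abs(win - bg)
    if dev.max() <= 1e-9:
        raise DetectionError("flat window: no corner marker found")
    try:
        thr = threshold_otsu(dev)
    except ValueError as exc:
        raise DetectionError("flat window: no corner marker found") from exc
    mask = dev > thr
    labels, n = ndimage.label(mask)
    if n == 0:
        raise DetectionError("no connected blob in window")
    centre = np.array([(win.shape[0] - 1) / 2.0, (win.shape[1] - 1) / 2.0])
    centroids = ndimage.center_of_mass(dev, labels, index=range(1, n + 1))
    sizes = ndimage.sum_labels(mask, labels, index=range(1, n + 1))
    best, best_d = None, np.inf
    for lab, (cy, cx) in enumerate(centroids, start=1):
        if sizes[lab - 1] < 4:        # ignore speckle
            continue
        d = np.hypot(cy - centre[0], cx - centre[1])
        if d < best_d:
            best, best_d = lab, d
    if best is None:
        raise DetectionError("no blob larger than speckle in window")
    sel = labels == best
    # reject pure-noise windows: the blob must stand clearly above the
    # robust border-noise scale
    noise_mad = 1.4826 * float(np.median(np.abs(border - bg)))
    if dev[sel].mean() < 6.0 * max(noise_mad, 1e-9):
        raise DetectionError("no marker blob above the noise floor")
    # include the sub-threshold partial-coverage edge pixels, which carry
    # the sub-pixel information of the marker boundary
    sel = ndimage.binary_dilation(sel)
    wsum = dev[sel].sum()
    rows, cols = np.nonzero(sel)
    cy = float((rows * dev[sel]).sum() / wsum)
    cx = float((cols * dev[sel]).sum() / wsum)
    return (r0 + cy, c0 + cx)


# --------------------------------------------------------------------------
# similarity calibration
# --------------------------------------------------------------------------

def fit_calibration(corners_detected, corners_model) -> CalibrationTransform:
    """Least-squares similarity fit: 4 model corners (mm) -> 4 detected (px).

    ``corners_detected`` are (row, col) pixels; ``corners_model`` are
    phantom-plane (x, y) mm.  Raises :class:`FitError` for degenerate
    (collinear or coincident) configurations.
    """
    det = np.asarray(corners_detected, dtype=float)
    mod = np.asarray(corners_model, dtype=float)
    if det.shape != (4, 2) or mod.shape != (4, 2):
        raise FitError("exactly four (row, col) / (x, y) corner pairs required")
    for pts in (det, mod):
        d = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(d, tol=1e-6 * max(1.0, np.abs(pts).max())) < 2:
            raise FitError("corner points are collinear or coincident")

    dst = np.column_stack([det[:, 1], -det[:, 0]])    # image xy = (col, -row)
    if hasattr(SimilarityTransform, "from_estimate"):
        tform = SimilarityTransform.from_estimate(mod, dst)
        ok = bool(tform)
    else:  # skimage < 0.26
        tform = SimilarityTransform()
        ok = tform.estimate(mod, dst)
    if not ok or not np.isfinite(tform.scale) or tform.scale <= 0:
        raise FitError("similarity fit failed")
    pred = tform(mod)
    residual = float(np.sqrt(np.mean(np.sum((pred - dst) ** 2, axis=1))))
    t_col, t_negrow = tform.translation
    return CalibrationTransform(
        scale=float(tform.scale),
        rotation_deg=float(np.rad2deg(tform.rotation)),
        translation=(float(-t_negrow), float(t_col)),
        residual=residual,
    )


def nominal_transform(geometry: ph.BeamGeometry,
                      imager: ph.ImagerSpec) -> CalibrationTransform:
    """Transform of a perfectly aligned phantom at nominal geometry."""
    m = ph.magnification(geometry, imager)
    rows, cols = imager.n_pixels
    return CalibrationTransform(
        scale=m / imager.pixel_pitch,
        rotation_deg=0.0,
        translation=((rows - 1) / 2.0, (cols - 1) / 2.0),
    )


def calibrate(image: PortalImage, layout: ph.PhantomLayout,
              geometry: ph.BeamGeometry | None = None,
              corner_seeds=None, window: int | None = None,
              iterations: int = 2) -> CalibrationTransform:
    """Full corner calibration of one image.

    ``corner_seeds`` are optional approximate (row, col) clicks for the
    markers ordered ne, nw, sw, se (the manual workflow); by default the
    nominal projection of the layout markers seeds the search.  A second
    pass re-refines the corners with seeds from the first fit.
    """
    geometry = geometry or ph.BeamGeometry()
    markers = layout.corner_markers
    model = np.array([mk.center for mk in markers])
    if window is None:
        scale0 = ph.magnification(geometry, image.imager) / image.imager.pixel_pitch
        window = int(3.5 * ph.MARKER_SIZE * scale0) | 1
    if corner_seeds is None:
        nom = nominal_transform(geometry, image.imager)
        seeds = [nom.to_pixels(*mk.center) for mk in markers]
    else:
        seeds = [tuple(s) for s in corner_seeds]
        if len(seeds) != 4:
            raise FitError("four corner seeds required (ne, nw, sw, se)")

    transform = None
    for it in range(max(1, iterations)):
        detected = [refine_corner(image, s, window=window) for s in seeds]
        transform = fit_calibration(detected, model)
        seeds = [transform.to_pixels(*mk.center) for mk in markers]
        # after the first pass the seeds are centred; shrink the window to
        # just over the marker size for the final refinement
        window = int(2.0 * ph.MARKER_SIZE * transform.scale) | 1
    return transform


# --------------------------------------------------------------------------
# element localization
# --------------------------------------------------------------------------

def locate_elements(transform: CalibrationTransform, layout: ph.PhantomLayout,
                    imager: ph.ImagerSpec,
                    margin_frac: float = 0.15) -> dict[str, ElementROI]:
    """Map every layout element to pixel bounds through the fitted transform.

    ``margin_frac`` (>= 0.10) of the shorter element side, plus the slack
    introduced by the fitted rotation, is absorbed into the interior margin
    so interior sampling never touches an element edge.

    Raises :class:`CoverageError` when an ROI leaves the image.
    """
    rows, cols = imager.n_pixels
    th = abs(np.deg2rad(transform.rotation_deg))
    c, s = np.cos(th), np.sin(th)
    rois: dict[str, ElementROI] = {}
    for e in layout.elements:
        x0, y0, x1, y1 = e.bounds()
        corners = [transform.to_pixels(x, y)
                   for x, y in ((x0, y0), (x0, y1), (x1, y0), (x1, y1))]
        rr = [p[0] for p in corners]
        cc = [p[1] for p in corners]
        r0, r1 = int(np.floor(min(rr))), int(np.ceil(max(rr)))
        c0, c1 = int(np.floor(min(cc))), int(np.ceil(max(cc)))
        if r0 < 0 or c0 < 0 or r1 > rows or c1 > cols:
            raise CoverageError(f"ROI of element {e.id} leaves the image")
        # inscribed half-sides of the rotated element, pixels
        w_px = (x1 - x0) * transform.scale
        h_px = (y1 - y0) * transform.scale
        hw_in = (w_px / 2) * c - (h_px / 2) * s
        hh_in = (h_px / 2) * c - (w_px / 2) * s
        inner = max(2.0, 2 * min(hw_in, hh_in))
        # outer bbox half-sides minus inscribed half-sides = rotation slack
        slack = max((r1 - r0) / 2 - hh_in, (c1 - c0) / 2 - hw_in, 0.0)
        margin = int(np.ceil(slack + margin_frac * inner))
        margin = min(margin, (min(r1 - r0, c1 - c0) - 1) // 2)
        rois[e.id] = ElementROI(element_id=e.id, pixel_bounds=(r0, c0, r1, c1),
                                interior_margin=max(margin, 1))
    return rois


def roi_mean(image: PortalImage, roi: ElementROI) -> float:
    """Mean gray value over the interior of an ROI."""
    sl = roi.interior_slices()
    return float(np.asarray(image.pixels, dtype=float)[sl].mean())


# --------------------------------------------------------------------------
# polarity
# --------------------------------------------------------------------------

def detect_polarity(image: PortalImage, rois: dict[str, ElementROI]) -> str:
    """Detect gray-scale polarity from the 0 % vs 50 % copper steps.

    Returns ``attenuation_dark`` (normal: more absorption is darker) or
    ``attenuation_bright`` (gray-scale-reversed export).  Raises
    :class:`PolarityError` when the step difference is below the noise
    floor (e.g. a uniform image).
    """
    px = np.asarray(image.pixels, dtype=float)
    means, varis, ns = [], [], []
    for key in ("cu_00", "cu_50"):
        if key not in rois:
            raise PolarityError(f"calibrated ROI {key!r} missing")
        sl = rois[key].interior_slices()
        patch = px[sl]
        means.append(patch.mean())
        varis.append(patch.var())
        ns.append(patch.size)
    diff = means[0] - means[1]           # open step minus 50 % step
    floor = 3.0 * np.sqrt(varis[0] / ns[0] + varis[1] / ns[1])
    if abs(diff) <= max(floor, 1e-9):
        raise PolarityError("0% and 50% steps indistinguishable: "
                            "polarity indeterminate")
    return "attenuation_dark" if diff > 0 else "attenuation_bright"


def normalize_polarity(image: PortalImage,
                       rois: dict[str, ElementROI]) -> tuple[PortalImage, str]:
    """Return (polarity-normalized image, detected polarity).

    All downstream analyses consume the normalized (attenuation-dark)
    image, so metrics agree between an image and its gray-scale-reversed
    twin.
    """
    polarity = detect_polarity(image, rois)
    if polarity == "attenuation_bright":
        return invert_polarity(image), polarity
    return image, polarity
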