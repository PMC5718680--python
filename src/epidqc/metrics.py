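"""The QA analysis core: linearity, local linearity, SNR, low contrast, MTF.

All analyzers consume a polarity-normalized image (more attenuation =
darker; see :func:`epidqc.registration.normalize_polarity`) together with
the calibrated element ROIs / transform.

Definitions
-----------
Signal linearity: mean gray value of each of the 10 copper steps, an 11th
point at 45 % absorption interpolated as the mean of the 40 % and 50 %
step means, an ordinary least-squares line through the 11 points, and the
maximum |measured - fitted| deviation expressed as a percentage of the
fitted gray range (a scale-free figure, so baselines transfer between
imagers and exposures).

SNR: per copper step, ``mean / variance`` of the interior gray values --
the mean-over-sigma-squared form is the convention this phantom's analysis
software prints; the more conventional ``mean / sigma`` is available via
``convention="std"``.  The summary value is the arithmetic mean over the
10 steps.

Low contrast: per hole, |mean(hole interior) - mean(surrounding annulus)|,
tabulated on the 6-column x 5-row grid (rows share a diameter, columns a
depth); a relative version (fraction of the local background) is kept
alongside because it is exposure-invariant.

MTF: per bar-pattern frequency, the Michelson contrast transmitted by the
detector relative to the fully-modulating object pattern (object contrast
k = 1 for the metal/gap lamellae, so the raw MTF equals the image
contrast).  The default estimator fits a blurred-bar profile model (square
wave x Gaussian line-spread x pixel aperture) to the pixels of each
segment at the known geometry and reports the peak Michelson contrast of
the fitted aperture-free profile; this estimates the contrast of the
continuous blurred wave, the quantity the square-wave oracle computes.
The literal stripe-mean estimator (mean gray of lamellae = maxima, mean
gray of gaps = minima) is available via ``method="stripe_mean"``; it
systematically reads low once the blur approaches the stripe width (by
2/pi-squared vs 4/pi Fourier weights in the sinusoid limit), which is why
it is not the default.  Curves are normalized to the smallest available
frequency per orientation; MTF(0.5) is interpolated in log-frequency.
No square-wave-to-sine (Coltman) correction is applied: the figure is a
bar-pattern contrast transfer, and the oracle is defined identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from . import phantom as ph
from .errors import AnalysisError, GeometryError, SaturationError
from .registration import CalibrationTransform, ElementROI, roi_mean
from .simulate import MAX_GRAY, PortalImage

__all__ = [
    "LinearityResult",
    "LocalLinearityResult",
    "SNRResult",
    "LowContrastResult",
    "OrientationMTF",
    "MTFResult",
    "linearity",
    "local_linearity",
    "snr",
    "low_contrast",
    "mtf",
]

#: interpolated absorption point added to the copper wedge curve
INTERPOLATED_ABSORPTION = 0.45
#: saturation guard: fraction of ROI pixels allowed at the gray ceiling
SATURATION_FRACTION = 0.01


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _interior(image: PortalImage, roi: ElementROI) -> np.ndarray:
    return np.asarray(image.pixels, dtype=float)[roi.interior_slices()]

def _check_saturation(patch: np.ndarray, what: str) -> None:
    frac = float(np.mean(patch >= MAX_GRAY - 0.5))
    if frac >= SATURATION_FRACTION:
        raise SaturationError(
            f"{what}: {frac:.1%} of pixels at the gray ceiling "
            "(over-exposed acquisition)")

def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and intercept of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)

def _max_deviation_pct(x, y, slope, intercept):
    """Max |measured - fitted| as a percentage of the fitted gray range."""
    fitted = slope * x + intercept
    rng = abs(slope) * (x.max() - x.min())
    if rng == 0:
        raise AnalysisError("degenerate fit: zero gray range across steps")
    dev = np.abs(y - fitted)
    i = int(np.argmax(dev))
    return float(dev[i] / rng * 100.0), i


# --------------------------------------------------------------------------
# linearity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LinearityResult:
    step_absorptions: tuple[float, ...]   # 11 fractions incl. interpolated 0.45
    step_means: tuple[float, ...]         # gray units
    slope: float
    intercept: float
    max_deviation: float                  # percent of fitted gray range
    worst_absorption: float


def linearity(image: PortalImage, rois: dict[str, ElementROI],
              layout: ph.PhantomLayout) -> LinearityResult:
    """Copper-wedge signal linearity (11-point regression).

    Raises :class:`SaturationError` when >= 1 % of any step's interior
    pixels sit at the gray ceiling.
    """
    steps = layout.copper_steps
    fracs, means = [], []
    for e in steps:
        patch = _interior(image, rois[e.id])
        _check_saturation(patch, f"copper step {e.id}")
        fracs.append(e.attenuation_fraction)
        means.append(float(patch.mean()))
    m40 = means[fracs.index(0.40)]
    m50 = means[fracs.index(0.50)]
    fracs.append(INTERPOLATED_ABSORPTION)
    means.append((m40 + m50) / 2.0)       # linear interpolation midpoint
    order = np.argsort(fracs)
    x = np.asarray(fracs, dtype=float)[order]
    y = np.asarray(means, dtype=float)[order]
    slope, intercept = _ols_line(x, y)
    max_dev, i = _max_deviation_pct(x, y, slope, intercept)
    return LinearityResult(
        step_absorptions=tuple(x), step_means=tuple(y),
        slope=slope, intercept=intercept,
        max_deviation=max_dev, worst_absorption=float(x[i]),
    )


@dataclass(frozen=True)
class LocalLinearityResult:
    per_block: dict[str, float]           # block -> max deviation, percent
    worst_block: str
    worst_deviation: float


def local_linearity(image: PortalImage, rois: dict[str, ElementROI],
                    layout: ph.PhantomLayout) -> LocalLinearityResult:
    """Per-brass-block 4-point linearity; the worst block is the output."""
    per_block: dict[str, float] = {}
    for name, steps in layout.brass_blocks.items():
        usable = [e for e in steps if e.id in rois]
        if len(usable) < 4:
            raise AnalysisError(f"brass block {name}: fewer than 4 usable steps")
        x, y = [], []
        for e in usable:
            patch = _interior(image, rois[e.id])
            _check_saturation(patch, f"brass step {e.id}")
            x.append(e.attenuation_fraction)
            y.append(float(patch.mean()))
        x, y = np.asarray(x), np.asarray(y)
        slope, intercept = _ols_line(x, y)
        per_block[name], _ = _max_deviation_pct(x, y, slope, intercept)
    worst = max(per_block, key=per_block.get)
    return LocalLinearityResult(per_block=per_block, worst_block=worst,
                                worst_deviation=per_block[worst])


# --------------------------------------------------------------------------
# SNR
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SNRResult:
    step_absorptions: tuple[float, ...]   # the 10 copper fractions
    per_step_snr: tuple[float, ...]
    mean_snr: float
    convention: str                       # "variance" (mean/var) or "std"
    infinite: bool = False                # any step had zero variance


def snr(image: PortalImage, rois: dict[str, ElementROI],
        layout: ph.PhantomLayout, convention: str = "variance") -> SNRResult:
    """Per-copper-step signal-to-noise ratio and its 10-step average.

    ``convention="variance"`` returns mean/variance (the convention this
    phantom's analysis prints); ``"std"`` returns mean/sigma.  A noise-free
    (zero-variance) step yields an infinite SNR with the ``infinite`` flag
    set rather than an exception.
    """
    if convention not in ("variance", "std"):
        raise ValueError(f"unknown SNR convention {convention!r}")
    fracs, values = [], []
    infinite = False
    for e in layout.copper_steps:
        patch = _interior(image, rois[e.id])
        mean = float(patch.mean())
        var = float(patch.var())          # population variance over the ROI
        denom = var if convention == "variance" else np.sqrt(var)
        if denom == 0.0:
            values.append(np.inf)
            infinite = True
        else:
            values.append(mean / denom)
        fracs.append(e.attenuation_fraction)
    return SNRResult(
        step_absorptions=tuple(fracs), per_step_snr=tuple(values),
        mean_snr=float(np.mean(values)), convention=convention,
        infinite=infinite,
    )


# --------------------------------------------------------------------------
# low contrast
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LowContrastResult:
    grid: np.ndarray            # 5 rows x 6 cols contrast difference, gray units
    grid_relative: np.ndarray   # same, as a fraction of the local background
    detectable: np.ndarray      # bool grid (3-sigma criterion); False where vacant
    populated: int              # number of non-vacant cells (27)
    threshold_sigma: float


def low_contrast(image: PortalImage, transform: CalibrationTransform,
                 layout: ph.PhantomLayout, annulus_gap_px: float = 2.0,
                 annulus_width_px: float = 5.0,
                 threshold_sigma: float = 3.0) -> LowContrastResult:
    """Contrast difference of each hole against its surrounding annulus.

    The annulus starts ``annulus_gap_px`` outside the hole radius and is
    ``annulus_width_px`` wide; annulus pixels that fall inside any other
    test element (padded by 0.75 mm) are clipped away, and a
    :class:`GeometryError` is raised if fewer than 10 annulus pixels
    survive.  A hole is flagged detectable when its contrast exceeds
    ``threshold_sigma`` standard errors of the hole-vs-annulus mean
    difference.
    """
    px = np.asarray(image.pixels, dtype=float)
    rows_n, cols_n = px.shape
    grid = np.full((5, 6), np.nan)
    grid_rel = np.full((5, 6), np.nan)
    detect = np.zeros((5, 6), dtype=bool)
    col_x = {x: j for j, x in enumerate(ph.HOLE_COLUMNS_X)}
    row_y = {y: i for i, y in enumerate(ph.HOLE_ROWS_Y)}

    others = [e for e in layout.elements]
    for hole in layout.holes:
        r_c, c_c = transform.to_pixels(*hole.center)
        r_hole = hole.hole_diameter / 2.0 * transform.scale
        r_in = r_hole + annulus_gap_px
        r_out = r_in + annulus_width_px
        ext = int(np.ceil(r_out)) + 1
        r0, r1 = int(np.floor(r_c)) - ext, int(np.ceil(r_c)) + ext + 1
        c0, c1 = int(np.floor(c_c)) - ext, int(np.ceil(c_c)) + ext + 1
        if r0 < 0 or c0 < 0 or r1 > rows_n or c1 > cols_n:
            raise GeometryError(f"annulus of {hole.id} leaves the image")
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d2 = (rr - r_c) ** 2 + (cc - c_c) ** 2
        hole_mask = d2 <= (0.7 * r_hole) ** 2
        if not hole_mask.any():           # tiny hole: take the nearest pixel
            hole_mask = d2 == d2.min()
        ann_mask = (d2 >= r_in ** 2) & (d2 <= r_out ** 2)

        # clip annulus pixels lying inside any other element (pad 0.75 mm)
        X, Y = transform.to_phantom(rr[ann_mask], cc[ann_mask])
        keep = np.ones(X.shape, dtype=bool)
        for e in others:
            if e.id == hole.id:
                continue
            x0, y0, x1, y1 = e.bounds()
            if (max(abs(x0 - hole.center[0]), abs(x1 - hole.center[0])) > 60 and
                    max(abs(y0 - hole.center[1]), abs(y1 - hole.center[1])) > 60):
                continue
            inside = ((X >= x0 - 0.75) & (X <= x1 + 0.75) &
                      (Y >= y0 - 0.75) & (Y <= y1 + 0.75))
            keep &= ~inside
        ann_vals = px[r0:r1, c0:c1][ann_mask][keep]
        if ann_vals.size < 10:
            raise GeometryError(
                f"annulus of {hole.id} overlaps neighboring elements")
        hole_vals = px[r0:r1, c0:c1][hole_mask]

        contrast = abs(float(hole_vals.mean()) - float(ann_vals.mean()))
        background = float(ann_vals.mean())
        i, j = row_y[hole.center[1]], col_x[hole.center[0]]
        grid[i, j] = contrast
        grid_rel[i, j] = contrast / background if background > 0 else np.nan
        se = float(np.sqrt(ann_vals.var(ddof=1) if ann_vals.size > 1 else 0.0)
                   ) * np.sqrt(1.0 / hole_vals.size + 1.0 / ann_vals.size)
        detect[i, j] = contrast > threshold_sigma * se
    populated = int(np.sum(~np.isnan(grid)))
    return LowContrastResult(grid=grid, grid_relative=grid_rel,
                             detectable=detect, populated=populated,
                             threshold_sigma=threshold_sigma)


# --------------------------------------------------------------------------
# MTF
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationMTF:
    orientation: str
    frequencies: tuple[float, ...]        # lp/mm, ascending (this orientation)
    raw_contrast: tuple[float, ...]       # nan where invalid
    normalized: tuple[float, ...]         # 1.0 at the lowest valid frequency
    valid: tuple[bool, ...]
    above_nyquist: tuple[bool, ...]
    mtf50: float | None                   # lp/mm
    mtf50_reached: bool
    last_valid_frequency: float | None


@dataclass(frozen=True)
class MTFResult:
    frequencies: tuple[float, ...]        # all 18 layout frequencies
    in_plane: OrientationMTF
    cross_plane: OrientationMTF
    method: str


def _segment_samples(image, transform, seg, cross_margin_mm=1.5):
    """Pixels of one bar segment: modulation coordinate (mm) and gray value."""
    px = np.asarray(image.pixels, dtype=float)
    w, h = seg.extent
    cx, cy = seg.center
    corners = [transform.to_pixels(x, y) for x, y in
               ((cx - w / 2, cy - h / 2), (cx - w / 2, cy + h / 2),
                (cx + w / 2, cy - h / 2), (cx + w / 2, cy + h / 2))]
    r0 = max(0, int(np.floor(min(p[0] for p in corners))))
    r1 = min(px.shape[0], int(np.ceil(max(p[0] for p in corners))) + 1)
    c0 = max(0, int(np.floor(min(p[1] for p in corners))))
    c1 = min(px.shape[1], int(np.ceil(max(p[1] for p in corners))) + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    X, Y = transform.to_phantom(rr.ravel(), cc.ravel())
    if seg.orientation == "in_plane":
        mcoord = Y - (cy - seg.length / 2)
        cross = X - cx
    else:
        mcoord = X - (cx - seg.length / 2)
        cross = Y - cy
    period = 1.0 / seg.frequency
    # skip the outer half-period (>= 2 mm) at both ends and keep away from
    # the cross edges: outside the segment the field is open, so blur bleeds
    # a one-sided bias into edge samples
    m_margin = max(period / 2, 2.0)
    sel = ((np.abs(cross) <= seg.width / 2 - cross_margin_mm) &
           (mcoord >= m_margin) & (mcoord <= seg.length - m_margin))
    return mcoord[sel], px[r0:r1, c0:c1].ravel()[sel]


def _bar_model(period: float, sigma: float, aperture: float, k: int = 512):
    """One period of a unit square wave blurred by a Gaussian LSF and a
    box pixel aperture, sampled at k points (circular convolution)."""
    phase = (np.arange(k) + 0.5) / k
    s = (phase < 0.5).astype(float)
    if sigma > 0:
        s = ndimage.gaussian_filter1d(s, sigma=sigma / period * k, mode="wrap")
    if aperture > 0:
        size = max(1, int(round(aperture / period * k)))
        if size > 1:
            s = ndimage.uniform_filter1d(s, size=size, mode="wrap")
    return phase, s

def _model_at(phase_grid, model, m, period):
    ph_m = np.mod(m / period, 1.0)
    return np.interp(ph_m, phase_grid, model, period=1.0)

def _phase_correct(m, v, period):
    """Re-estimate the bar phase from the fundamental (tolerates the small
    residual shift the corner calibration leaves) and return shifted m."""
    e = np.exp(-2j * np.pi * m / period)
    s_ideal = (np.mod(m / period, 1.0) < 0.5).astype(float)
    z_meas = np.sum((v - v.mean()) * e)
    z_ref = np.sum((s_ideal - s_ideal.mean()) * e)
    if abs(z_ref) < 1e-9 or abs(z_meas) < 1e-12:
        return m
    ang = np.angle(z_meas / z_ref)
    if ang > np.pi / 2:
        ang -= np.pi
    elif ang < -np.pi / 2:
        ang += np.pi
    return m - ang / (2 * np.pi) * period


def _seg_rss(m, v, period, pixel_mm, sigma):
    """Least-squares offset/amplitude of the bar model at one sigma."""
    phase, model = _bar_model(period, sigma, pixel_mm)
    pred = _model_at(phase, model, m, period)
    A = np.column_stack([np.ones_like(pred), pred])
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    r = v - A @ coef
    return float(r @ r), coef


def _joint_sigma(samples, pixel_mm):
    """Shared line-spread sigma (phantom mm) over all segments of one
    orientation.

    The detector has a single LSF per direction, so sigma is estimated
    jointly: this keeps frequencies whose period is commensurate with the
    pixel grid (few distinct sample phases, sigma unidentifiable alone)
    pinned by the densely sampled low frequencies.  RSS(sigma) is not
    unimodal (a secondary minimum exists at large blur), so the global
    minimum is bracketed on a coarse log grid before local refinement.
    """
    def total(sigma):
        return sum(_seg_rss(m, v, p, pixel_mm, sigma)[0] for m, v, p in samples)

    grid = np.concatenate([[0.0], np.geomspace(0.02, 3.0, 30)])
    costs = [total(s) for s in grid]
    i = int(np.argmin(costs))
    sigma_hat = float(grid[i])
    if 0 < i < len(grid) - 1:
        res = optimize.minimize_scalar(
            total, bounds=(grid[i - 1], grid[i + 1]),
            method="bounded", options={"xatol": 1e-4})
        if float(res.fun) <= costs[i]:
            sigma_hat = float(res.x)
    return sigma_hat


def _profile_contrast(m, v, period, pixel_mm, sigma):
    """Michelson contrast of the fitted aperture-free (pre-sampling)
    profile of one segment, given the shared LSF sigma."""
    _, coef = _seg_rss(m, v, period, pixel_mm, sigma)
    a, b = coef
    _, psf_only = _bar_model(period, sigma, 0.0)
    prof = a + b * psf_only
    hi, lo = float(prof.max()), float(prof.min())
    if hi + lo <= 0:
        return 0.0
    return abs(hi - lo) / (hi + lo)


def _stripe_mean_contrast(m, v, period):
    """Literal maxima/minima stripe means (central 60 % of each stripe)."""
    half = period / 2.0
    k = np.floor(m / half).astype(int)
    centre_off = np.abs(m - (k + 0.5) * half)
    use = centre_off <= 0.3 * half
    bar_vals = v[use & (k % 2 == 0)]
    gap_vals = v[use & (k % 2 == 1)]
    if bar_vals.size < 3 or gap_vals.size < 3:
        return np.nan
    # per-stripe means, then the mean over stripes
    bars, gaps = [], []
    for kk in np.unique(k[use]):
        vals = v[use & (k == kk)]
        if vals.size < 1:
            continue
        (bars if kk % 2 == 0 else gaps).append(float(vals.mean()))
    if not bars or not gaps:
        return np.nan
    minima = float(np.mean(bars))        # metal bars are dark
    maxima = float(np.mean(gaps))
    if maxima + minima <= 0:
        return np.nan
    return abs(maxima - minima) / (maxima + minima)


def _orientation_mtf(image, transform, layout, orientation, method):
    segs = layout.segments(orientation)
    pixel_mm = 1.0 / transform.scale      # pixel pitch in phantom mm
    freqs, raw, valid, above = [], [], [], []
    samples: list[tuple] = []             # (m, v, period) of valid segments
    for seg in segs:
        period = 1.0 / seg.frequency
        stripe_px = transform.scale * period / 2.0
        is_above = seg.frequency > transform.scale / 2.0
        ok = stripe_px >= 1.5
        value = np.nan
        if ok:
            m, v = _segment_samples(image, transform, seg)
            if m.size < 20:
                ok = False
            elif method == "stripe_mean":
                value = _stripe_mean_contrast(m, v, period)
                ok = np.isfinite(value)
            else:
                m = _phase_correct(m, v, period)
                samples.append((m, v, period))
        freqs.append(seg.frequency)
        raw.append(value)
        valid.append(bool(ok))
        above.append(bool(is_above))

    if method == "profile_fit" and samples:
        sigma_hat = _joint_sigma(samples, pixel_mm)
        it = iter(samples)
        for i in range(len(freqs)):
            if valid[i]:
                m, v, period = next(it)
                raw[i] = _profile_contrast(m, v, period, pixel_mm, sigma_hat)

    raw = np.asarray(raw)
    norm = np.full_like(raw, np.nan)
    first = next((i for i, ok in enumerate(valid) if ok and raw[i] > 0), None)
    if first is None:
        raise AnalysisError(f"no valid bar-pattern frequency in {orientation}")
    norm[np.asarray(valid)] = raw[np.asarray(valid)] / raw[first]

    # MTF(0.5): log-frequency interpolation among valid, sub-Nyquist points
    use = [i for i in range(len(freqs)) if valid[i] and not above[i]
           and np.isfinite(norm[i])]
    mtf50, reached = None, False
    last_valid = freqs[use[-1]] if use else None
    for a_i, b_i in zip(use[:-1], use[1:]):
        na, nb = norm[a_i], norm[b_i]
        if na >= 0.5 > nb:
            la, lb = np.log(freqs[a_i]), np.log(freqs[b_i])
            mtf50 = float(np.exp(la + (0.5 - na) * (lb - la) / (nb - na)))
            reached = True
            break
    return OrientationMTF(
        orientation=orientation, frequencies=tuple(freqs),
        raw_contrast=tuple(float(x) for x in raw),
        normalized=tuple(float(x) for x in norm),
        valid=tuple(valid), above_nyquist=tuple(above),
        mtf50=mtf50, mtf50_reached=reached, last_valid_frequency=last_valid,
    )


def mtf(image: PortalImage, transform: CalibrationTransform,
        layout: ph.PhantomLayout, method: str = "profile_fit") -> MTFResult:
    """Bar-pattern MTF in both detector directions.

    ``method="profile_fit"`` (default) fits the blurred-bar model per
    segment; ``method="stripe_mean"`` uses the literal lamella/gap stripe
    means.  Frequencies whose projected stripe width is below 1.5 px are
    flagged invalid (not an error); frequencies above the imager's Nyquist
    limit are flagged and excluded from the MTF(0.5) search.
    """
    if method not in ("profile_fit", "stripe_mean"):
        raise ValueError(f"unknown MTF method {method!r}")
    return MTFResult(
        frequencies=layout.frequencies,
        in_plane=_orientation_mtf(image, transform, layout, "in_plane", method),
        cross_plane=_orientation_mtf(image, transform, layout, "cross_plane", method),
        method=method,
    )


# --------------------------------------------------------------------------
# CSV export
# --------------------------------------------------------------------------

def mtf_to_csv(result: MTFResult) -> str:
    """The MTF curves as CSV (one row per orientation x frequency)."""
    lines = ["orientation,frequency_lp_per_mm,raw_contrast,normalized,"
             "valid,above_nyquist"]
    for o in (result.in_plane, result.cross_plane):
        for f, raw, norm, ok, above in zip(o.frequencies, o.raw_contrast,
                                           o.normalized, o.valid,
                                           o.above_nyquist):
            lines.append(f"{o.orientation},{f:.6g},{raw:.6g},{norm:.6g},"
                         f"{int(ok)},{int(above)}")
    return "\n".join(lines) + "\n"


def low_contrast_to_csv(result: LowContrastResult) -> str:
    """The 5x6 contrast grid as CSV (rows = diameter, columns = depth)."""
    lines = ["row," + ",".join(f"col{j}" for j in range(6))]
    for i in range(5):
        cells = ["" if not np.isfinite(x) else f"{x:.6g}"
                 for x in result.grid[i]]
        lines.append(f"{i}," + ",".join(cells))
    return "\n".join(lines) + "\n"
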