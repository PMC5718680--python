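"""Synthetic portal-image renderer with known ground truth.

No public archive of megavoltage portal images of the QC phantom exists, so
the toolkit ships a physics-light simulator: each test element contributes a
fixed attenuation fraction (the digital model takes the 6 MV fractions as
given), the phantom is centrally projected onto the panel with the
``SID / 100 cm`` magnification, detector blur is a parameterized
point-spread function applied in detector-plane millimetres, and noise is an
additive Gaussian read component plus a Gaussian approximation of the
Poisson (fluence-proportional) component.  Exposure in monitor units acts as
a pure gain.  The rendered image carries its ground truth in the metadata,
which is what makes parameter-recovery tests possible.

Rendering is done by super-sampled rasterization of the attenuation map
(default 4x the pixel density) followed by PSF convolution and block-mean
downsampling onto the pixel grid, which emulates the pixel aperture and
avoids aliasing bias in the bar patterns.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import phantom as ph
from .errors import CoverageError

__all__ = [
    "MAX_GRAY",
    "PointSpreadFunction",
    "NoiseModel",
    "SyntheticTruth",
    "PortalImage",
    "render",
    "square_wave_response",
    "invert_polarity",
]

#: gray ceiling of the 16-bit unsigned convention used throughout
MAX_GRAY = 65535.0


@dataclass(frozen=True)
class PointSpreadFunction:
    """Detector blur model; ``sigma`` is in detector-plane mm.

    ``sigma`` may be a scalar or an ``(sigma_x, sigma_y)`` pair for an
    anisotropic focal spot (x = detector column / cross-plane direction,
    y = detector row / in-plane direction).
    """

    kind: str = "delta"                      # "delta" | "gaussian"
    sigma: float | tuple[float, float] = 0.0

    def __post_init__(self):
        if self.kind not in ("delta", "gaussian"):
            raise ValueError(f"unknown PSF kind {self.kind!r}")
        sx, sy = self.sigma_xy
        if sx < 0 or sy < 0:
            raise ValueError("PSF sigma must be non-negative")

    @property
    def sigma_xy(self) -> tuple[float, float]:
        if np.isscalar(self.sigma):
            return (float(self.sigma), float(self.sigma))
        sx, sy = self.sigma
        return (float(sx), float(sy))

    def sigma_along(self, axis: str) -> float:
        """1-D cross-section sigma along ``"x"`` or ``"y"`` (mm)."""
        if self.kind == "delta":
            return 0.0
        return self.sigma_xy[0 if axis == "x" else 1]


@dataclass(frozen=True)
class NoiseModel:
    """Additive detector noise: read noise + Gaussian-approximated Poisson.

    Pixel variance is ``read_sigma**2 + gain * signal`` (gray units).
    """

    read_sigma: float = 0.0
    gain: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.read_sigma < 0 or self.gain < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth acquisition parameters of one rendered image."""

    psf: PointSpreadFunction = PointSpreadFunction()
    noise: NoiseModel = NoiseModel()
    rotation_deg: float = 0.0                  # phantom rotation, CCW, degrees
    translation: tuple[float, float] = (0.0, 0.0)   # phantom-plane mm
    mu: float = 1.0                            # monitor units (pure gain)
    polarity: str = "attenuation_dark"
    background_level: float = 3000.0           # open-field gray at 1 MU

    def __post_init__(self):
        if abs(self.rotation_deg) > 10.0:
            raise ValueError("misalignment rotation limited to +/-10 degrees")
        if self.mu <= 0:
            raise ValueError("monitor units must be positive")
        if self.polarity not in ("attenuation_dark", "attenuation_bright"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


@dataclass
class PortalImage:
    """A 2-D grayscale portal image plus the imager that produced it."""

    pixels: np.ndarray
    imager: ph.ImagerSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("portal image must be a 2-D array")
        if tuple(self.pixels.shape) != tuple(self.imager.n_pixels):
            raise ValueError(
                f"pixel array {self.pixels.shape} does not match imager "
                f"grid {self.imager.n_pixels}")
        if np.any(np.asarray(self.pixels, dtype=float) < 0):
            raise ValueError("gray values must be non-negative")


# --------------------------------------------------------------------------
# misalignment transform (phantom plane)
# --------------------------------------------------------------------------

def _forward(truth: SyntheticTruth, x, y):
    """Phantom point -> misaligned phantom point: p' = R(theta) p + t."""
    th = np.deg2rad(truth.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    tx, ty = truth.translation
    return (c * x - s * y + tx, s * x + c * y + ty)


def _bar_integral(t, half):
    """Integral from 0 to t of the unit bar pattern (bar on [0, half),
    gap on [half, 2*half), ...)."""
    t = np.maximum(t, 0.0)
    n = np.floor(t / half)
    frac = t - n * half
    return np.ceil(n / 2.0) * half + np.where(n % 2 == 0, frac, 0.0)


def _bar_coverage(mcoord, frequency, width):
    """Fraction of a cell of the given width (centered on mcoord) covered
    by metal bars — analytic anti-aliasing of the bar edges."""
    half = 0.5 / frequency
    lo = mcoord - width / 2.0
    hi = mcoord + width / 2.0
    return (_bar_integral(hi, half) - _bar_integral(lo, half)) / width


def _check_coverage(layout, geometry, imager, truth):
    half_field = geometry.field_size_isocenter * 10.0 / 2.0  # mm at 100 cm
    m = ph.magnification(geometry, imager)
    rows, cols = imager.n_pixels
    half_u = cols * imager.pixel_pitch / 2.0
    half_w = rows * imager.pixel_pitch / 2.0
    for e in layout.elements:
        x0, y0, x1, y1 = e.bounds()
        for x, y in ((x0, y0), (x0, y1), (x1, y0), (x1, y1)):
            xp, yp = _forward(truth, x, y)
            if abs(xp) > half_field or abs(yp) > half_field:
                raise CoverageError(
                    f"element {e.id} falls outside the "
                    f"{geometry.field_size_isocenter} cm field")
            if abs(xp * m) > half_u or abs(yp * m) > half_w:
                raise CoverageError(
                    f"element {e.id} projects outside the "
                    f"{rows}x{cols} panel")


# --------------------------------------------------------------------------
# attenuation rasterization
# --------------------------------------------------------------------------

def _rasterize_attenuation(layout, geometry, imager, truth, supersample):
    """Attenuation fraction sampled on the super-sampled detector grid."""
    m = ph.magnification(geometry, imager)
    rows, cols = imager.n_pixels
    ss = supersample
    nr, nc = rows * ss, cols * ss
    q = imager.pixel_pitch / ss

    # detector-plane mm of fine-grid sample centers
    u = (np.arange(nc, dtype=np.float64) + 0.5) * q - cols * imager.pixel_pitch / 2.0
    w = -((np.arange(nr, dtype=np.float64) + 0.5) * q - rows * imager.pixel_pitch / 2.0)

    # inverse misalignment: p = R(-theta) (p_det / M - t)
    th = np.deg2rad(truth.rotation_deg)
    c, s = np.cos(th), np.sin(th)
    tx, ty = truth.translation
    a = u / m - tx                      # (nc,)
    b = w / m - ty                      # (nr,)
    # X = c*a + s*b ; Y = -s*a + c*b  (broadcast to (nr, nc))
    A = np.zeros((nr, nc), dtype=np.float32)

    def slice_for(x0, y0, x1, y1, pad=2):
        """Fine-grid index window covering a phantom-plane rect."""
        js, is_ = [], []
        for x, y in ((x0, y0), (x0, y1), (x1, y0), (x1, y1)):
            xp, yp = _forward(truth, x, y)
            js.append((xp * m + cols * imager.pixel_pitch / 2.0) / q - 0.5)
            is_.append((-yp * m + rows * imager.pixel_pitch / 2.0) / q - 0.5)
        j0 = max(0, int(np.floor(min(js))) - pad)
        j1 = min(nc, int(np.ceil(max(js))) + pad + 1)
        i0 = max(0, int(np.floor(min(is_))) - pad)
        i1 = min(nr, int(np.ceil(max(is_))) + pad + 1)
        return slice(i0, i1), slice(j0, j1)

    def local_coords(si, sj):
        X = c * a[None, sj] + s * b[si, None]
        Y = -s * a[None, sj] + c * b[si, None]
        return X, Y

    for e in layout.elements:
        if e.kind == "lamella_block":
            for seg in e.segments:
                sw, sh = seg.extent
                scx, scy = seg.center
                si, sj = slice_for(scx - sw / 2, scy - sh / 2,
                                   scx + sw / 2, scy + sh / 2)
                X, Y = local_coords(si, sj)
                inside = ((np.abs(X - scx) <= sw / 2) &
                          (np.abs(Y - scy) <= sh / 2))
                if seg.orientation == "in_plane":
                    mcoord = Y - (scy - seg.length / 2)
                else:
                    mcoord = X - (scx - seg.length / 2)
                # effective cell width along the modulation axis (the fine
                # cell projected through the misalignment rotation)
                cell = (q / m) * (abs(c) + abs(s))
                cov = _bar_coverage(mcoord, seg.frequency, cell)
                patch = A[si, sj]
                patch[inside] = ph.LAMELLA_FRACTION * cov[inside]
                A[si, sj] = patch
        elif e.kind == "hole":
            x0, y0, x1, y1 = e.bounds()
            si, sj = slice_for(x0, y0, x1, y1)
            X, Y = local_coords(si, sj)
            r = e.hole_diameter / 2.0
            inside = (X - e.center[0]) ** 2 + (Y - e.center[1]) ** 2 <= r * r
            patch = A[si, sj]
            patch[inside] = e.attenuation_fraction
            A[si, sj] = patch
        else:
            x0, y0, x1, y1 = e.bounds()
            si, sj = slice_for(x0, y0, x1, y1)
            X, Y = local_coords(si, sj)
            inside = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1)
            patch = A[si, sj]
            patch[inside] = e.attenuation_fraction
            A[si, sj] = patch
    return A


def render(layout: ph.PhantomLayout, geometry: ph.BeamGeometry,
           imager: ph.ImagerSpec, truth: SyntheticTruth,
           supersample: int = 4, quantize: bool = True) -> PortalImage:
    """Render a synthetic portal image of the phantom.

    Noise is reproducible for a fixed ``truth.noise.seed``.  With
    ``quantize=True`` (default) pixels are rounded to 16-bit unsigned;
    ``quantize=False`` keeps float pixels, which preserves exact gain
    relations (e.g. MU scaling) that rounding would break.

    Raises :class:`CoverageError` when the field or panel does not cover
    every test element.
    """
    _check_coverage(layout, geometry, imager, truth)
    A = _rasterize_attenuation(layout, geometry, imager, truth, supersample)

    signal = 1.0 - A
    sx, sy = truth.psf.sigma_xy
    if truth.psf.kind == "gaussian" and (sx > 0 or sy > 0):
        q = imager.pixel_pitch / supersample
        # sigma order (rows, cols): rows blur along y, cols along x
        signal = ndimage.gaussian_filter(signal, sigma=(sy / q, sx / q),
                                         mode="nearest")

    rows, cols = imager.n_pixels
    ss = supersample
    pixels = signal.reshape(rows, ss, cols, ss).mean(axis=(1, 3)).astype(np.float64)
    pixels *= truth.background_level * truth.mu

    noise = truth.noise
    if noise.read_sigma > 0 or noise.gain > 0:
        rng = np.random.default_rng(noise.seed)
        var = noise.read_sigma ** 2 + noise.gain * np.clip(pixels, 0, None)
        pixels = pixels + rng.standard_normal(pixels.shape) * np.sqrt(var)

    if truth.polarity == "attenuation_bright":
        pixels = MAX_GRAY - pixels
    pixels = np.clip(pixels, 0.0, MAX_GRAY)
    if quantize:
        pixels = np.round(pixels).astype(np.uint16)

    meta = {
        "truth": dataclasses.asdict(truth),
        "vendor": imager.vendor_label,
        "mu": truth.mu,
    }
    return PortalImage(pixels=pixels, imager=imager, metadata=meta)


def invert_polarity(image: PortalImage) -> PortalImage:
    """Gray-scale-reversed twin of an image (p -> MAX_GRAY - p)."""
    px = image.pixels
    if px.dtype == np.uint16:
        inv = (int(MAX_GRAY) - px.astype(np.int64)).astype(np.uint16)
    else:
        inv = MAX_GRAY - np.asarray(px, dtype=float)
    meta = dict(image.metadata)
    meta["polarity_inverted"] = not meta.get("polarity_inverted", False)
    return PortalImage(pixels=inv, imager=image.imager, metadata=meta)


# --------------------------------------------------------------------------
# square-wave contrast oracle
# --------------------------------------------------------------------------

def square_wave_response(psf: PointSpreadFunction, frequency: float,
                         samples_per_period: int = 256,
                         axis: str = "x") -> float:
    """Contrast fraction transmitted for a bar pattern of a given frequency.

    Brute force: a 1-D unit square wave of period ``1/frequency`` is sampled
    densely (>= 100 points per period), convolved with the explicit PSF
    kernel, and the Michelson contrast ``(max-min)/(max+min)`` of the
    blurred wave is divided by that of the ideal wave (which is 1).  This is
    the independent oracle the image-domain MTF analyzer is tested against.

    ``frequency`` and the PSF sigma must be in the same plane/units (both
    detector-plane mm here).  ``axis`` selects the cross-section of an
    anisotropic PSF.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    if samples_per_period < 100:
        raise ValueError("oracle requires >= 100 samples per period")
    sigma = psf.sigma_along(axis)
    if sigma == 0.0:
        return 1.0
    period = 1.0 / frequency
    step = period / samples_per_period
    # enough periods that the central one is free of end effects; the
    # kernel support runs to 8 sigma so truncation cannot leave a
    # spurious contrast floor at strong blur
    n_periods = 3 + 2 * int(np.ceil(8.0 * sigma / period + 1))
    n = n_periods * samples_per_period
    # integer index arithmetic keeps the wave exactly balanced (floating
    # floor() at the bar edges would leave a spurious contrast floor)
    wave = ((np.arange(n) % samples_per_period)
            < samples_per_period // 2).astype(float)

    half = int(np.ceil(8.0 * sigma / step))
    k = np.arange(-half, half + 1) * step
    kernel = np.exp(-0.5 * (k / sigma) ** 2)
    kernel /= kernel.sum()
    blurred = np.convolve(wave, kernel, mode="same")

    mid = n // 2
    centre = blurred[mid - samples_per_period // 2: mid + samples_per_period // 2]
    hi, lo = float(centre.max()), float(centre.min())
    if hi + lo == 0:
        return 0.0
    return (hi - lo) / (hi + lo)
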