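# Methods

This note records the models, conventions and numerical choices behind
`epidqc`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate conventions and projection model

Phantom-plane coordinates have their origin at the phantom center,
x = cross-plane, y = in-plane, in millimetres. Pixels are (row, col),
0-based, row 0 at the top; +x maps to +col and +y to −row. The projection
reference plane is the phantom *base*: at the nominal 95.2 cm SSD the
4.8 cm slab puts its base at the 100 cm isocenter plane, so a detector at
source-to-imager distance SID sees the phantom magnified by M = SID/100.
Projection is a central (pin-hole) projection; the phantom is treated as
thin (all elements projected from the reference plane), which is consistent
with the phantom's focused element geometry and keeps the renderer and the
analyzers exactly inverse to one another.

## The digital phantom

Element positions in millimetres are not published for the physical device,
so the layout is a documented constant block (`epidqc.phantom`), chosen to
respect the published census and quadrant arrangement: line patterns in the
upper two quadrants, the extra brass pair in the third quadrant, the hole
array in the fourth, copper wedges in a central strip, four corner markers.
All analyses depend only on the layout being shared between renderer and
analyzer, not on the particular millimetre values. Specific choices where
only ranges or counts are published:

* **Hole array**: 6 columns × 5 rows with 3 vacant cells. Which cells are
  vacant is not published; this model leaves the smallest-diameter row
  vacant over the three shallowest columns. Diameters per row and depths
  per column are geometric ladders over the published extremes
  (1.1–15 mm; 0.5–4.8 mm). Hole contrast is modelled as an attenuation
  offset of 0.01 per mm of depth; only ratios matter to the analyses.
* **Bar patterns**: 14 blocks carrying 18 distinct frequencies on a
  geometric ladder from 0.167 to 3.5 lp/mm. Four blocks are arranged
  diagonally and carry one segment per orientation so a single exposure
  yields both MTF curves; two of those and the outer block of each oriented
  group carry two frequencies. The lowest frequency (the normalization
  anchor) lives on a diagonal block so both orientations include it.
  Bars are modelled as fully modulating (object contrast k = 1), so the
  image Michelson contrast of a block *is* its contrast-transfer value.
* **Brass steps** use exactly {0.10, 0.20, 0.30, 0.40} ("approximately" in
  the vendor description): synthetic ground truth must be exact.
* The copper fractions {0, .05, …, .40, .50} sum to 2.30 — the 45 % step
  does not exist in hardware, which is why the analysis interpolates it.

## Synthetic renderer

Pixel value = polarity-map(background × MU × (1 − A) ⊗ PSF) + noise, where
A is the attenuation fraction at the projected point. Rendering
super-samples the attenuation map at 4× the pixel density, applies the
Gaussian PSF in detector-plane millimetres (anisotropic σx/σy supported,
since focal-spot asymmetry makes resolution direction-dependent), and
block-means down to the pixel grid — i.e. the pixel aperture is modelled
as a box. Bar patterns are rasterized with analytic partial-cell coverage;
binary rasterization would leave ±2 % contrast jitter at frequencies
commensurate with the fine grid. Noise is additive Gaussian read noise
plus a Gaussian approximation of the Poisson fluence component
(variance = gain × signal); no detector model is published for this class
of device, and the tests only need a controllable, seedable variance.
Monitor units act as a pure gain (integration behavior is not modelled).
Default gray depth is 16-bit unsigned with background 3000 gray at 1 MU,
leaving headroom to 15 MU without saturation. `quantize=False` keeps float
pixels; exactness properties (MU scaling, polarity round trips) hold
exactly only there, since rounding breaks exact proportionality.

Out of scope: radiation transport, scatter/glare/lag, flood- and dark-field
calibration, spectral attenuation of the metals (fractions are taken as
given). Consequently, green tests say the *analysis pipeline* recovers
known ground truth through a linear, shift-invariant, well-behaved imager;
they do not certify behavior on a real detector with structured
non-uniformity, glare or non-Gaussian LSF tails.

## Registration

Corner markers are refined to sub-pixel centroids: Otsu threshold of
|gray − window-border median| (polarity-agnostic), nearest connected
component to the window center, one binary dilation to pull in the
partial-coverage edge pixels, intensity-weighted centroid. A least-squares
similarity transform (uniform scale, rotation, translation — the phantom is
rigid and the projection isotropic) is fitted between the four model
corners and the four detections; the RMS corner residual is reported and
flags misidentification (a 5 px error on one corner gives residual > 1 px).
Seeds default to the nominal projection (fully automatic mode); a second
pass re-seeds from the first fit, which tolerates misalignments larger
than the first window margin. Manual click seeds are accepted for the
classical workflow. Rotation is reported in degrees, positive
counter-clockwise in the image. Recovery measured on noise-free renders:
≤ 0.005° and ≤ 0.01 px over ±3° and 20 px offsets; ≤ 0.03° at 2 % noise.

Polarity is detected by comparing the 0 % and 50 % copper steps; if the
50 % step is brighter the image is gray-scale-reversed and all analyses
consume the inverted image. A difference below 3 standard errors raises an
indeterminate-polarity error rather than guessing.

## Metric definitions and numerical choices

* **Deviation percentages** (linearity, local linearity) are normalized by
  the fitted gray range of each regression. No normalization is published;
  a scale-free figure is required for baselines to transfer across
  imagers, exposures and gray-scale gains (the tests assert exact
  invariance under affine gray transforms).
* **SNR** is mean/variance as printed by this phantom family's software,
  with mean/σ behind `convention="std"` — the printed convention is kept
  as the default deliberately, flagged here because it is not the textbook
  definition. Zero variance (synthetic noise-free input) reports infinity
  with a flag, not an exception.
* **Low contrast**: hole interior sampled at 0.7× the projected radius;
  annulus from radius + 2 px, 5 px wide, clipped against every other
  element footprint (padded 0.75 mm); fewer than 10 surviving annulus
  pixels is a geometry error. Detectability: contrast > 3 standard errors
  of the hole-vs-annulus mean difference. The absolute grid (gray units)
  scales with exposure; the relative grid (fraction of local background)
  is the exposure-invariant figure.
* **MTF**: the default `profile_fit` estimator fits
  a + b · (square ⊗ Gaussian(σ) ⊗ box(pixel)) to each segment's pixels at
  the calibrated geometry (bar phase re-estimated from the fundamental to
  absorb residual calibration shift) and reports the Michelson contrast of
  the fitted aperture-free profile — the contrast of the continuous blurred
  wave, which is what the independent square-wave convolution oracle
  computes. σ is one number per orientation, fitted jointly across all
  valid segments: the detector has a single line-spread per direction, and
  the joint fit keeps frequencies whose period is commensurate with the
  pixel grid (few distinct sampling phases) identifiable. RSS(σ) has a
  secondary minimum at large blur, so the global minimum is bracketed on a
  coarse log grid before local refinement. The literal stripe-mean
  estimator (`method="stripe_mean"`) is retained for comparison; Fourier
  analysis shows full-stripe means read the contrast low by up to 8/π²
  versus 4/π (≈ 36 % relative) once blur dominates, so it is not the
  default. No square-wave→sine (Coltman) correction is applied: the figure
  is a bar-pattern contrast transfer, and the oracle is defined
  identically. Stripes narrower than 1.5 px are flagged invalid per
  frequency (not an error); frequencies above the Nyquist limit are
  flagged and excluded from the MTF(0.5) search; MTF(0.5) is interpolated
  in log-frequency, and "not reached" is reported with the last valid
  frequency instead of a number.
* Each image is analyzed independently (single-exposure workflow; no
  multi-image averaging).

## Baselines and trends

The first accepted analysis of an imager becomes its baseline. Default
tolerances — rotation 0.5°, linearity and local-linearity deviation
2 percentage points, mean SNR 10 %, MTF(0.5) 10 % — are editable opinions
offered as a starting point, not vendor limits. Comparison is two-level
(within tolerance passes, within twice warns, beyond fails; overall =
worst parameter) and symmetric in sign. Series are stored append-only as
newline-delimited JSON per imager identity with strictly increasing
timestamps; trend statistics are mean, SD, OLS drift slope per day with a
t-based 95 % band, out-of-tolerance counts, and a flag when the linear
projection over a configurable horizon (default 30 days) would leave
tolerance.

## Problem sizes used

Tests and the acceptance script render full-size 1024² Elekta-geometry
images (4096² super-sampled rasters, ≈ 0.6 s each); noise-recovery runs use
50 seeds on 1024² flat fields, drift recovery 30 daily records, the corner
Monte-Carlo 100 seeds on 61² windows. The whole suite completes in about a
minute on one CPU.

## Known limitations

* The millimetre layout is canonical, not the vendor's drawing; analyses of
  *real* phantom images would require re-measuring the constant block.
* The Varian-geometry preset at its nominal 150 cm SID cannot cover the
  phantom (a real hardware limitation); the simulation preset retracts the
  panel to 105 cm.
* The MTF profile fit assumes a Gaussian line-spread family when
  extrapolating from the sampled to the continuous profile; strongly
  non-Gaussian detectors would bias the aperture correction.
* BMP I/O is 8-bit and lossy by format; TIFF/DICOM round-trip bit-exactly.
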