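"""Digital model of the EPID QC phantom and the portal-imaging geometry.

The phantom is a 25 x 25 x 4.8 cm slab carrying five families of test
elements used for routine image-quality QA of electronic portal imaging
devices (EPIDs):

* two copper step wedges (10 steps, 0-50 % attenuation) for signal
  linearity and SNR,
* six four-step brass blocks (~10/20/30/40 %) probing the spatial
  uniformity ("local dependence") of the linearity,
* 27 shallow holes in an aluminum slab (a Las-Vegas-style tool) for
  low-contrast resolution,
* 14 line-pair (lamella) blocks spanning 18 spatial frequencies for
  bar-pattern MTF in both detector directions,
* four corner markers used to register the phantom on the image.

Coordinate conventions
----------------------
Phantom plane: origin at the phantom center, ``x`` along the cross-plane
axis, ``y`` along the in-plane axis, millimetres.  Pixel coordinates are
``(row, col)``, 0-based, row 0 at the top; +x maps to +col and +y maps to
-row.  The projection reference plane is the phantom *base*, placed at the
isocenter (95.2 cm SSD + 4.8 cm thickness = 100 cm), so a detector at
source-to-imager distance ``SID`` sees the phantom magnified by
``M = SID / 100``.

The vendor does not publish element positions in millimetres; the constant
block below fixes one self-consistent canonical table (line patterns in the
upper quadrants, the brass pair in the third quadrant, the hole array in
the fourth) that the synthetic renderer and the analyzers share.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import LayoutError, OutOfFieldError

__all__ = [
    "TestElement",
    "LamellaSegment",
    "PhantomLayout",
    "ImagerSpec",
    "BeamGeometry",
    "build_layout",
    "project_to_pixels",
    "unproject_from_pixels",
    "magnification",
    "nyquist_frequency",
    "isocenter_field_of_view",
    "effective_pixel_size",
    "save_layout",
    "load_layout",
    "ELEKTA",
    "SIEMENS",
    "VARIAN",
    "VARIAN_SIM",
    "IMAGER_PRESETS",
]

# --------------------------------------------------------------------------
# Canonical layout constants (phantom-plane mm)
# --------------------------------------------------------------------------

#: outer dimensions of the slab (x, y, thickness), mm
OUTER_DIMS_MM = (250.0, 250.0, 48.0)

#: nominal source-to-surface distance of the front plate, cm
BASE_PLANE_SSD_CM = 95.2

#: phantom thickness, cm (base plate sits at SSD + thickness = isocenter)
THICKNESS_CM = 4.8

#: copper step attenuation fractions for a 6 MV beam, 5 % increments with
#: the 45 % step omitted in hardware (it is interpolated by the analysis)
COPPER_FRACTIONS = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.50)
COPPER_STEP_SIZE = 18.0      # mm, square step
COPPER_STEP_PITCH = 20.0     # mm, center-to-center

#: brass step attenuation fractions (nominally "approximately" these; the
#: digital model uses the exact values so synthetic ground truth is exact)
BRASS_FRACTIONS = (0.10, 0.20, 0.30, 0.40)
BRASS_STEP_SIZE = 9.0        # mm, each of the 2x2 sub-steps
BRASS_STEP_OFFSET = 5.0      # mm, sub-step center offset from block center
#: block id -> center; four corners plus two extra blocks in quadrant 3
BRASS_BLOCK_CENTERS = {
    "ne": (92.0, 92.0),
    "nw": (-92.0, 92.0),
    "sw": (-92.0, -92.0),
    "se": (92.0, -92.0),
    "q3a": (-50.0, -92.0),
    "q3b": (-92.0, -50.0),
}

#: corner markers (the four corner elements clicked during calibration)
MARKER_SIZE = 10.0           # mm
MARKER_FRACTION = 0.45
MARKER_CENTERS = {
    "ne": (112.0, 112.0),
    "nw": (-112.0, 112.0),
    "sw": (-112.0, -112.0),
    "se": (112.0, -112.0),
}

#: low-contrast hole array: 6 columns x 5 rows, 3 cells vacant.
#: Holes in a row share the diameter, holes in a column share the depth.
#: Only the ranges are published (1.1-15 mm diameter, 0.5-4.8 mm depth);
#: intermediate values are geometric interpolations.
HOLE_COLUMNS_X = (10.0, 28.0, 46.0, 64.0, 82.0, 100.0)
HOLE_ROWS_Y = (-14.0, -28.5, -43.0, -57.5, -72.0)
HOLE_DIAMETERS = tuple(map(float, np.geomspace(1.1, 15.0, 5)))  # per row, top -> bottom
HOLE_DEPTHS = tuple(map(float, np.geomspace(0.5, 4.8, 6)))      # per column, left -> right
#: attenuation per mm of removed aluminum (digital-model constant)
HOLE_ATTENUATION_PER_MM = 0.01
#: vacant cells (row_index, col_index): the smallest-diameter row over the
#: three shallowest columns.  Which 3 of the 30 grid cells are empty is an
#: implementer's choice of this digital model.
HOLE_VACANT_CELLS = ((0, 0), (0, 1), (0, 2))

#: the 18 bar-pattern frequencies (lp/mm), geometric ladder over the
#: published range 0.167-3.5 lp/mm
LAMELLA_FREQUENCIES = tuple(map(float, np.geomspace(0.167, 3.5, 18)))
LAMELLA_SEGMENT_LENGTH = 18.0   # mm along the modulation axis (>= 3 periods)
LAMELLA_SEGMENT_WIDTH = 10.0    # mm across
#: metal-bar attenuation: the lamellae are modelled as fully modulating
#: (object contrast k = 1), so the image Michelson contrast of a block IS
#: its raw contrast-transfer value
LAMELLA_FRACTION = 1.0
_SEG_GAP = 3.0                  # mm between segments inside a block

#: lamella block plan: (block_id, placement, frequency indices, block center)
#: placement "diagonal" blocks carry one segment per orientation and serve
#: both MTF curves; "in_plane"/"cross_plane" blocks belong to one oriented
#: group.  Dual blocks (two frequency indices) are the outer block of each
#: oriented group plus two of the diagonal blocks, giving 14 blocks and 18
#: distinct frequencies.
LAMELLA_BLOCK_PLAN = (
    ("diag_a", "diagonal", (0, 1), (-75.0, 36.0)),
    ("diag_b", "diagonal", (2, 3), (75.0, 36.0)),
    ("diag_c", "diagonal", (4,), (-21.0, 36.0)),
    ("diag_d", "diagonal", (5,), (21.0, 36.0)),
    ("ip_outer", "in_plane", (6, 8), (22.0, 62.0)),
    ("ip_1", "in_plane", (10,), (48.0, 62.0)),
    ("ip_2", "in_plane", (12,), (66.0, 62.0)),
    ("ip_3", "in_plane", (14,), (84.0, 62.0)),
    ("ip_4", "in_plane", (16,), (102.0, 62.0)),
    ("cp_outer", "cross_plane", (7, 9), (-22.0, 62.0)),
    ("cp_1", "cross_plane", (11,), (-46.0, 62.0)),
    ("cp_2", "cross_plane", (13,), (-68.0, 62.0)),
    ("cp_3", "cross_plane", (15,), (-90.0, 62.0)),
    ("cp_4", "cross_plane", (17,), (-112.0, 62.0)),
)

ELEMENT_KINDS = ("copper_step", "brass_step", "hole", "lamella_block", "corner_marker")
ORIENTATIONS = ("in_plane", "cross_plane", "diagonal")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LamellaSegment:
    """One axis-aligned bar-pattern segment inside a lamella block.

    ``orientation`` names the MTF curve the segment feeds: ``in_plane``
    segments modulate along y (horizontal bars), ``cross_plane`` segments
    modulate along x (vertical bars).  The first metal bar starts at the
    low-coordinate end of the segment.
    """

    frequency: float                 # lp/mm
    orientation: str                 # "in_plane" | "cross_plane"
    center: tuple[float, float]      # phantom-plane mm
    length: float                    # mm along the modulation axis
    width: float                     # mm across the bars

    @property
    def extent(self) -> tuple[float, float]:
        """(w, h) footprint in phantom mm."""
        if self.orientation == "in_plane":
            return (self.width, self.length)
        return (self.length, self.width)


@dataclass(frozen=True)
class TestElement:
    """A single physical test element of the phantom."""

    id: str
    kind: str
    center: tuple[float, float]           # phantom-plane mm
    extent: tuple[float, float]           # (w, h) mm footprint
    attenuation_fraction: float | None = None
    hole_diameter: float | None = None    # mm (holes only)
    hole_depth: float | None = None       # mm (holes only)
    frequencies: tuple[float, ...] | None = None   # lp/mm (lamella only)
    orientation: str | None = None        # lamella only
    group: str | None = None              # block membership label
    segments: tuple[LamellaSegment, ...] | None = None  # lamella only

    def __post_init__(self):
        if self.kind not in ELEMENT_KINDS:
            raise LayoutError(f"unknown element kind {self.kind!r}")
        if self.attenuation_fraction is not None and not (
            0.0 <= self.attenuation_fraction <= 0.5
        ):
            raise LayoutError(
                f"{self.id}: attenuation fraction {self.attenuation_fraction} "
                "outside [0, 0.5]"
            )
        if self.kind == "hole":
            if not (1.1 <= self.hole_diameter <= 15.0):
                raise LayoutError(f"{self.id}: hole diameter out of range")
            if not (0.5 <= self.hole_depth <= 4.8):
                raise LayoutError(f"{self.id}: hole depth out of range")
        if self.kind == "lamella_block":
            if self.orientation not in ORIENTATIONS:
                raise LayoutError(f"{self.id}: bad orientation {self.orientation!r}")
            for f in self.frequencies:
                if not (0.167 <= f <= 3.5):
                    raise LayoutError(f"{self.id}: frequency {f} out of range")

    def bounds(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) footprint in phantom mm."""
        cx, cy = self.center
        w, h = self.extent
        return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


@dataclass(frozen=True)
class PhantomLayout:
    """Canonical positions and attenuations of every test element."""

    elements: tuple[TestElement, ...]
    outer_dims: tuple[float, float, float] = OUTER_DIMS_MM
    base_plane_ssd: float = BASE_PLANE_SSD_CM

    def of_kind(self, kind: str) -> list[TestElement]:
        return [e for e in self.elements if e.kind == kind]

    @property
    def copper_steps(self) -> list[TestElement]:
        """The 10 copper steps sorted by attenuation fraction."""
        return sorted(self.of_kind("copper_step"),
                      key=lambda e: e.attenuation_fraction)

    @property
    def brass_blocks(self) -> dict[str, list[TestElement]]:
        """Brass steps grouped by block, each sorted by attenuation."""
        blocks: dict[str, list[TestElement]] = {}
        for e in self.of_kind("brass_step"):
            blocks.setdefault(e.group, []).append(e)
        for steps in blocks.values():
            steps.sort(key=lambda e: e.attenuation_fraction)
        return blocks

    @property
    def holes(self) -> list[TestElement]:
        return self.of_kind("hole")

    @property
    def lamella_blocks(self) -> list[TestElement]:
        return self.of_kind("lamella_block")

    @property
    def corner_markers(self) -> list[TestElement]:
        """The four corner markers ordered ne, nw, sw, se."""
        order = {"ne": 0, "nw": 1, "sw": 2, "se": 3}
        return sorted(self.of_kind("corner_marker"),
                      key=lambda e: order[e.group])

    @property
    def frequencies(self) -> tuple[float, ...]:
        """All distinct lamella frequencies, ascending."""
        out: set[float] = set()
        for e in self.lamella_blocks:
            out.update(e.frequencies)
        return tuple(sorted(out))

    def segments(self, orientation: str) -> list[LamellaSegment]:
        """All bar-pattern segments feeding one MTF orientation."""
        if orientation not in ("in_plane", "cross_plane"):
            raise ValueError(f"orientation must be in_plane/cross_plane, got {orientation!r}")
        segs = []
        for e in self.lamella_blocks:
            segs.extend(s for s in e.segments if s.orientation == orientation)
        return sorted(segs, key=lambda s: s.frequency)

    def validate(self) -> None:
        """Check every structural invariant; raise LayoutError on failure."""
        cu = self.copper_steps
        if len(cu) != 10 or tuple(e.attenuation_fraction for e in cu) != COPPER_FRACTIONS:
            raise LayoutError("copper wedge must expose the 10 fractions 0-50%")
        blocks = self.brass_blocks
        if len(blocks) != 6:
            raise LayoutError("expected 6 brass blocks")
        for name, steps in blocks.items():
            if tuple(e.attenuation_fraction for e in steps) != BRASS_FRACTIONS:
                raise LayoutError(f"brass block {name} must have steps 10/20/30/40%")
        holes = self.holes
        if len(holes) != 27:
            raise LayoutError("expected 27 holes")
        by_row: dict[float, set[float]] = {}
        by_col: dict[float, set[float]] = {}
        for h in holes:
            by_row.setdefault(h.center[1], set()).add(h.hole_diameter)
            by_col.setdefault(h.center[0], set()).add(h.hole_depth)
        if any(len(v) != 1 for v in by_row.values()) or len(by_row) != 5:
            raise LayoutError("holes in one row must share a diameter (5 rows)")
        if any(len(v) != 1 for v in by_col.values()) or len(by_col) != 6:
            raise LayoutError("holes in one column must share a depth (6 columns)")
        lam = self.lamella_blocks
        if len(lam) != 14:
            raise LayoutError("expected 14 lamella blocks")
        if len(self.frequencies) != 18:
            raise LayoutError("expected 18 distinct lamella frequencies")
        n_diag = sum(1 for e in lam if e.orientation == "diagonal")
        if n_diag != 4:
            raise LayoutError("expected 4 diagonally-arranged dual-orientation blocks")
        if len(self.corner_markers) != 4:
            raise LayoutError("expected 4 corner markers")
        half_x, half_y = self.outer_dims[0] / 2, self.outer_dims[1] / 2
        for e in self.elements:
            x0, y0, x1, y1 = e.bounds()
            if x0 < -half_x or y0 < -half_y or x1 > half_x or y1 > half_y:
                raise LayoutError(f"element {e.id} extends beyond the slab")


@dataclass(frozen=True)
class ImagerSpec:
    """Vendor geometry of a flat-panel portal imager."""

    vendor_label: str
    n_pixels: tuple[int, int]            # (rows, cols)
    pixel_pitch: float                   # mm / pixel
    panel_extent: tuple[float, float]    # (w, h) cm = (cols, rows) direction
    source_to_detector: float            # cm
    polarity: str = "attenuation_dark"

    def __post_init__(self):
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")
        w_cm = self.n_pixels[1] * self.pixel_pitch / 10.0
        h_cm = self.n_pixels[0] * self.pixel_pitch / 10.0
        for stated, derived in ((self.panel_extent[0], w_cm), (self.panel_extent[1], h_cm)):
            if abs(stated - derived) / derived > 0.02:
                raise ValueError(
                    f"panel extent {stated} cm inconsistent with "
                    f"{derived:.2f} cm = n_pixels x pitch"
                )

    @property
    def pixel_density(self) -> float:
        """Sampling density at the detector plane, pixels/mm."""
        return 1.0 / self.pixel_pitch

    @property
    def nyquist(self) -> float:
        """Detector-plane Nyquist frequency, lp/mm."""
        return nyquist_frequency(self.pixel_density)


@dataclass(frozen=True)
class BeamGeometry:
    """Acquisition geometry of one phantom exposure."""

    ssd_phantom_surface: float = BASE_PLANE_SSD_CM   # cm
    field_size_isocenter: float = 26.0               # cm
    gantry_label: str = "G000"

    def __post_init__(self):
        if self.ssd_phantom_surface <= 0:
            raise ValueError("SSD must be positive")

    @property
    def reference_distance(self) -> float:
        """Source distance (cm) of the projection reference plane (phantom base)."""
        return self.ssd_phantom_surface + THICKNESS_CM


# --------------------------------------------------------------------------
# Layout construction
# --------------------------------------------------------------------------

def build_layout() -> PhantomLayout:
    """Build the canonical phantom layout.

    Returns a :class:`PhantomLayout` satisfying every structural invariant
    (validated before return).
    """
    elements: list[TestElement] = []

    # copper step wedges: 10 steps in a central horizontal strip
    xs = np.arange(-90.0, 91.0, COPPER_STEP_PITCH)
    for x, frac in zip(xs, COPPER_FRACTIONS):
        elements.append(TestElement(
            id=f"cu_{int(round(frac * 100)):02d}",
            kind="copper_step",
            center=(float(x), 0.0),
            extent=(COPPER_STEP_SIZE, COPPER_STEP_SIZE),
            attenuation_fraction=frac,
            group="copper_wedge",
        ))

    # brass blocks: 2x2 sub-steps; 10/20% on the upper row, 30/40% lower
    sub_offsets = ((-1, 1), (1, 1), (-1, -1), (1, -1))
    for name, (bx, by) in BRASS_BLOCK_CENTERS.items():
        for (ox, oy), frac in zip(sub_offsets, BRASS_FRACTIONS):
            elements.append(TestElement(
                id=f"brass_{name}_{int(round(frac * 100))}",
                kind="brass_step",
                center=(bx + ox * BRASS_STEP_OFFSET, by + oy * BRASS_STEP_OFFSET),
                extent=(BRASS_STEP_SIZE, BRASS_STEP_SIZE),
                attenuation_fraction=frac,
                group=f"brass_{name}",
            ))

    # low-contrast hole array
    for r, (y, diam) in enumerate(zip(HOLE_ROWS_Y, HOLE_DIAMETERS)):
        for c, (x, depth) in enumerate(zip(HOLE_COLUMNS_X, HOLE_DEPTHS)):
            if (r, c) in HOLE_VACANT_CELLS:
                continue
            elements.append(TestElement(
                id=f"hole_r{r}c{c}",
                kind="hole",
                center=(x, y),
                extent=(diam, diam),
                attenuation_fraction=HOLE_ATTENUATION_PER_MM * depth,
                hole_diameter=float(diam),
                hole_depth=float(depth),
                group="hole_array",
            ))

    # lamella blocks
    for block_id, placement, freq_idx, center in LAMELLA_BLOCK_PLAN:
        freqs = tuple(LAMELLA_FREQUENCIES[i] for i in freq_idx)
        segments = _block_segments(placement, freqs, center)
        w = max(s.center[0] + s.extent[0] / 2 for s in segments) - \
            min(s.center[0] - s.extent[0] / 2 for s in segments)
        h = max(s.center[1] + s.extent[1] / 2 for s in segments) - \
            min(s.center[1] - s.extent[1] / 2 for s in segments)
        elements.append(TestElement(
            id=f"lamella_{block_id}",
            kind="lamella_block",
            center=center,
            extent=(w, h),
            frequencies=freqs,
            orientation=placement,
            group=f"lamella_{block_id}",
            segments=tuple(segments),
        ))

    # corner markers
    for name, center in MARKER_CENTERS.items():
        elements.append(TestElement(
            id=f"marker_{name}",
            kind="corner_marker",
            center=center,
            extent=(MARKER_SIZE, MARKER_SIZE),
            attenuation_fraction=MARKER_FRACTION,
            group=name,
        ))

    layout = PhantomLayout(elements=tuple(elements))
    layout.validate()
    return layout


def _block_segments(placement, freqs, center):
    """Lay out the bar segments of one lamella block around its center."""
    L, W, g = LAMELLA_SEGMENT_LENGTH, LAMELLA_SEGMENT_WIDTH, _SEG_GAP
    cx, cy = center
    segs: list[LamellaSegment] = []

    def seg(freq, orient, sx, sy):
        return LamellaSegment(frequency=freq, orientation=orient,
                              center=(sx, sy), length=L, width=W)

    if placement == "diagonal":
        # one in-plane + one cross-plane segment per frequency, in an x row
        widths = []
        for f in freqs:
            widths.extend([W, L])          # in_plane is W wide, cross_plane L wide
        total = sum(widths) + g * (len(widths) - 1)
        x = cx - total / 2
        i = 0
        for f in freqs:
            for orient, w in (("in_plane", W), ("cross_plane", L)):
                segs.append(seg(f, orient, x + w / 2, cy))
                x += w + g
                i += 1
    elif placement == "in_plane":
        # segments side by side along x
        total = len(freqs) * W + g * (len(freqs) - 1)
        x = cx - total / 2
        for f in freqs:
            segs.append(seg(f, "in_plane", x + W / 2, cy))
            x += W + g
    elif placement == "cross_plane":
        # segments stacked along y
        total = len(freqs) * W + g * (len(freqs) - 1)
        y = cy - total / 2
        for f in freqs:
            segs.append(seg(f, "cross_plane", cx, y + W / 2))
            y += W + g
    else:  # pragma: no cover
        raise LayoutError(f"unknown placement {placement!r}")
    return segs


# --------------------------------------------------------------------------
# Projection geometry
# --------------------------------------------------------------------------

def magnification(geometry: BeamGeometry, imager: ImagerSpec) -> float:
    """Central-projection magnification from the reference plane to the panel."""
    if imager.source_to_detector < geometry.reference_distance:
        raise ValueError("source-to-detector distance is inside the phantom")
    return imager.source_to_detector / geometry.reference_distance


def project_to_pixels(point, geometry: BeamGeometry, imager: ImagerSpec,
                      clip: bool = True):
    """Project a phantom-plane point (x, y) mm to fractional (row, col) pixels.

    The central ray maps to the panel center ((rows-1)/2, (cols-1)/2).
    Raises :class:`OutOfFieldError` when the projection leaves the panel
    (unless ``clip=False``).  Accepts scalars or arrays.
    """
    x = np.asarray(point[0], dtype=float)
    y = np.asarray(point[1], dtype=float)
    m = magnification(geometry, imager)
    rows, cols = imager.n_pixels
    col = (cols - 1) / 2.0 + m * x / imager.pixel_pitch
    row = (rows - 1) / 2.0 - m * y / imager.pixel_pitch
    if clip and (np.any(col < -0.5) or np.any(col > cols - 0.5)
                 or np.any(row < -0.5) or np.any(row > rows - 0.5)):
        raise OutOfFieldError(
            f"point {point} projects outside the {rows}x{cols} panel")
    if x.ndim == 0:
        return (float(row), float(col))
    return (row, col)


def unproject_from_pixels(pixel, geometry: BeamGeometry, imager: ImagerSpec):
    """Inverse of :func:`project_to_pixels`: (row, col) -> (x, y) phantom mm."""
    row = np.asarray(pixel[0], dtype=float)
    col = np.asarray(pixel[1], dtype=float)
    m = magnification(geometry, imager)
    rows, cols = imager.n_pixels
    x = (col - (cols - 1) / 2.0) * imager.pixel_pitch / m
    y = -(row - (rows - 1) / 2.0) * imager.pixel_pitch / m
    if row.ndim == 0:
        return (float(x), float(y))
    return (x, y)


def nyquist_frequency(pixel_density: float) -> float:
    """Nyquist frequency (lp/mm) of a sampling density given in pixels/mm."""
    if pixel_density <= 0:
        raise ValueError("pixel density must be positive")
    return pixel_density / 2.0


def isocenter_field_of_view(panel_side: float, sid: float) -> float:
    """Side (cm) of the panel area back-projected to the isocenter plane.

    ``panel_side`` is the physical panel side in cm and ``sid`` the
    source-to-imager distance in cm (must be >= 100, i.e. panel at or
    beyond the isocenter).
    """
    if sid < 100.0:
        raise ValueError("source-to-imager distance must be >= 100 cm")
    return panel_side * 100.0 / sid


def effective_pixel_size(panel_side_cm: float, n_pixels: int) -> float:
    """Detector pixel pitch (mm) implied by a panel side and pixel count."""
    if panel_side_cm <= 0 or n_pixels <= 0:
        raise ValueError("panel side and pixel count must be positive")
    return panel_side_cm * 10.0 / n_pixels


# --------------------------------------------------------------------------
# Vendor presets
# --------------------------------------------------------------------------

ELEKTA = ImagerSpec("elekta_iview", (1024, 1024), 0.4, (41.0, 41.0), 160.0)
SIEMENS = ImagerSpec("siemens_beamview", (1024, 1024), 0.4, (41.0, 41.0), 140.0)
#: nominal Varian geometry; the 25 cm phantom does NOT fit this panel at
#: 150 cm (a documented hardware limitation) — rendering raises a coverage
#: error here.
VARIAN = ImagerSpec("varian_asi1000", (768, 1024), 0.390625, (40.0, 30.0), 150.0)
#: Varian geometry with the panel retracted close to the isocenter, the
#: clinical workaround that makes the phantom fit.
VARIAN_SIM = ImagerSpec("varian_asi1000", (768, 1024), 0.390625, (40.0, 30.0), 105.0)

IMAGER_PRESETS = {
    "elekta": ELEKTA,
    "siemens": SIEMENS,
    "varian": VARIAN_SIM,
    "varian_nominal": VARIAN,
}


# --------------------------------------------------------------------------
# Layout serialization (structured text for third-party consumers)
# --------------------------------------------------------------------------

def layout_to_dict(layout: PhantomLayout) -> dict:
    """Plain-dict form of a layout (mm / lp/mm / dimensionless fractions)."""
    def elem(e: TestElement) -> dict:
        d = dataclasses.asdict(e)
        return {k: v for k, v in d.items() if v is not None}
    return {
        "units": {"length": "mm", "frequency": "lp/mm",
                  "attenuation": "fraction"},
        "outer_dims": list(layout.outer_dims),
        "base_plane_ssd_cm": layout.base_plane_ssd,
        "elements": [elem(e) for e in layout.elements],
    }


def layout_from_dict(data: dict) -> PhantomLayout:
    elements = []
    for d in data["elements"]:
        segs = d.pop("segments", None)
        if segs is not None:
            segs = tuple(LamellaSegment(
                frequency=s["frequency"], orientation=s["orientation"],
                center=tuple(s["center"]), length=s["length"], width=s["width"],
            ) for s in segs)
        if "frequencies" in d:
            d["frequencies"] = tuple(d["frequencies"])
        elements.append(TestElement(
            center=tuple(d.pop("center")), extent=tuple(d.pop("extent")),
            segments=segs, **d))
    layout = PhantomLayout(
        elements=tuple(elements),
        outer_dims=tuple(data["outer_dims"]),
        base_plane_ssd=data["base_plane_ssd_cm"],
    )
    layout.validate()
    return layout


def save_layout(layout: PhantomLayout, path) -> None:
    """Write the layout as YAML (``.yaml``/``.yml``) or JSON."""
    path = Path(path)
    data = layout_to_dict(layout)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


def load_layout(path) -> PhantomLayout:
    """Read a layout written by :func:`save_layout`."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return layout_from_dict(data)
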