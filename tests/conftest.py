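"""Shared fixtures: canonical layout and a small set of rendered images.

Renders are session-scoped because several test modules analyze the same
acquisition conditions; everything is generated at test time (no stored
image fixtures).
"""

import numpy as np
import pytest

import epidqc as e
from epidqc.simulate import NoiseModel, PointSpreadFunction, SyntheticTruth


@pytest.fixture(scope="session")
def layout():
    return e.build_layout()


@pytest.fixture(scope="session")
def geometry():
    return e.BeamGeometry()


@pytest.fixture(scope="session")
def image_ideal(layout, geometry):
    """Noise-free delta-PSF float render at nominal alignment (Elekta)."""
    return e.render(layout, geometry, e.ELEKTA, SyntheticTruth(), quantize=False)


@pytest.fixture(scope="session")
def result_ideal(image_ideal, layout, geometry):
    return e.analyze_image(image_ideal, layout=layout, geometry=geometry)


@pytest.fixture(scope="session")
def image_blur(layout, geometry):
    """Noise-free gaussian-blur (sigma 0.5 mm) float render."""
    truth = SyntheticTruth(psf=PointSpreadFunction("gaussian", 0.5))
    return e.render(layout, geometry, e.ELEKTA, truth, quantize=False)


@pytest.fixture(scope="session")
def image_noisy(layout, geometry):
    """Blurred render with 2 % read noise and fluence noise (uint16)."""
    truth = SyntheticTruth(psf=PointSpreadFunction("gaussian", 0.5),
                           noise=NoiseModel(read_sigma=60.0, gain=0.5, seed=3))
    return e.render(layout, geometry, e.ELEKTA, truth)


@pytest.fixture(scope="session")
def rotation_renders(layout, geometry):
    """Noise-free renders at rotations -3..3 deg with a 12/-20 px shift."""
    out = {}
    for rot in (-3.0, -1.0, 0.0, 1.0, 3.0):
        truth = SyntheticTruth(rotation_deg=rot, translation=(3.0, -5.0))
        out[rot] = (truth, e.render(layout, geometry, e.ELEKTA, truth,
                                    quantize=False))
    return out


@pytest.fixture(scope="session")
def nominal(geometry):
    return e.nominal_transform(geometry, e.ELEKTA)


@pytest.fixture(scope="session")
def rois_nominal(nominal, layout):
    return e.locate_elements(nominal, layout, e.ELEKTA)


def make_step_image(rois_nominal, step_values, base=3000.0, imager=None):
    """Flat image with prescribed gray values painted into copper-step ROIs.

    Used to drive the linearity/SNR analyzers with hand-chosen numbers.
    """
    imager = imager or e.ELEKTA
    px = np.full(imager.n_pixels, base)
    for key, value in step_values.items():
        r0, c0, r1, c1 = rois_nominal[key].pixel_bounds
        px[r0:r1, c0:c1] = value
    return e.PortalImage(pixels=px, imager=imager)
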