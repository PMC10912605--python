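"""Shared fixtures: desk-scale optics, prebuilt PSF stacks, a tiny PSF.

PSF builds are session-scoped because they are the expensive common
ingredient; the "tiny" PSF is a hand-made 3-plane stack small enough for
dense-matrix oracles.
"""

import numpy as np
import pytest

import lfcyto as lf


@pytest.fixture(scope="session")
def cfg_reduced():
    """Desk-scale optics: 512 px sensor at 9 µm, ±2 µm axial, 41 planes."""
    return lf.OpticalConfig.reduced()


@pytest.fixture(scope="session")
def psf_far(cfg_reduced):
    """Far-red (680 nm) PSF stack on the desk-scale grid."""
    return lf.build_psf_stack(cfg_reduced, channel=2)


@pytest.fixture(scope="session")
def op_far(psf_far):
    """Reusable linear-boundary forward operator for the 512 px grid."""
    return lf.LightFieldOperator(psf_far, shape=(512, 512))


@pytest.fixture(scope="session")
def cfg_smoke():
    """Very small grid (256 px at 18 µm) for I/O and CLI smoke tests."""
    return lf.OpticalConfig.reduced(sensor=256, pixel_cam=18.0,
                                    z_range=1.0, z_step=0.1)


@pytest.fixture(scope="session")
def tiny_psf():
    """Synthetic 3-plane 8×8 PSF for brute-force operator oracles."""
    rng = np.random.default_rng(42)
    yy, xx = np.mgrid[0:8, 0:8] - 3.5
    data = np.empty((3, 8, 8), dtype=np.float32)
    for k, (oy, ox, s) in enumerate([(-1.0, 0.5, 1.2), (0.0, 0.0, 0.9),
                                     (1.0, -0.5, 1.2)]):
        data[k] = np.exp(-(((yy - oy) ** 2 + (xx - ox) ** 2) / (2 * s ** 2)))
        data[k] += 0.01 * rng.uniform(size=(8, 8))
    data /= data[1].sum()
    return lf.PSFStack(data=data, z_step=0.5, voxel_xy=0.5, wavelength=680.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
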