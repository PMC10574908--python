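"""Shared fixtures: band-limited line patterns and a small simulated projection.

The line-pattern fixture is the resolution chart restricted to its
restorable band (0.6–2.5 lp/mm at 48 um pixels) and anti-aliased with a
1 px Gaussian, so its spectral content survives the blurs under test and
restoration quality is measurable against it.
"""

import numpy as np
import pytest
from scipy import ndimage

import adaptpsf as ap


@pytest.fixture(scope="session")
def line_pattern() -> np.ndarray:
    """Band-limited bar chart on [0, 1], 160x160."""
    raw = ap.generate_line_chart(
        frequencies=list(np.linspace(0.6, 2.5, 10)),
        pixel_pitch=0.048,
        group_height=16,
        width=192,
    )[:160, :160] / 4095.0
    return ndimage.gaussian_filter(raw, 1.0, mode="nearest")


@pytest.fixture(scope="session")
def line_pattern_adu(line_pattern) -> np.ndarray:
    """The same chart in 12-bit ADU units."""
    return line_pattern * 4095.0


@pytest.fixture(scope="session")
def detector_profiles():
    return ap.load_detector_profiles()


@pytest.fixture(scope="session")
def small_projection() -> np.ndarray:
    """Clean cone-beam projection of a 100-voxel die phantom, 128x160."""
    phantom = ap.build_dice_phantom(n_voxels=100)
    geom = ap.ProjectionGeometry(pixel_pitch=0.1, detector_shape=(128, 160), i0=3000.0)
    return ap.project_phantom(phantom, geom)


def replicate_blur(img: np.ndarray, sigma: float) -> np.ndarray:
    """Replicate-padded Gaussian blur matching the sweep's forward model."""
    return ndimage.gaussian_filter(img, sigma, mode="nearest", truncate=4.0)


def periodic_blur(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution via the FFT, for exact-inverse oracles."""
    from adaptpsf.restoration import psf_to_otf

    return np.real(np.fft.ifft2(np.fft.fft2(img) * psf_to_otf(kernel, img.shape)))
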