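"""Synthetic radiograph generation: phantoms, cone-beam projection, degradation.

Supplies everything needed to validate the estimation/restoration chain
without measured detector data:

* a voxelized PMMA die phantom (a solid cube with spherical pip recesses,
  giving the projection internal edges at several scales),
* a cone-beam Beer–Lambert projector (mono-energetic, no scatter) over a
  source / object / detector geometry specified by SOD and SDD,
* a bar-pattern line chart covering 0.6–5.0 lp/mm, the standard resolution
  fixture, and
* ``degrade_image``, which turns a clean projection into what a given
  detector would record: Gaussian PSF blur of the detector's LSF width
  followed by Poisson–Gaussian noise, clipped to the ADC range.

Detector profiles (scintillator thickness, pixel pitch, LSF sigma, noise
parameters) for a thin/medium/thick Gd2O2S:Tb scintillator family ship as
packaged YAML.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import ndimage

from .errors import InputError, ParameterError
from .noise_model import NoiseModel, synthesize_noise

__all__ = [
    "Phantom3D",
    "ProjectionGeometry",
    "DetectorProfile",
    "load_detector_profiles",
    "build_dice_phantom",
    "project_phantom",
    "generate_line_chart",
    "degrade_image",
    "FULL_SCALE_GEOMETRY",
    "DESK_SCALE_GEOMETRY",
]


@dataclass(frozen=True)
class Phantom3D:
    """Voxelized attenuation map.

    volume holds linear attenuation coefficients in 1/mm on a cubic voxel
    grid of pitch voxel_size (mm); materials maps tag names to coefficients.
    """

    volume: np.ndarray = field(repr=False)
    voxel_size: float = 0.1
    materials: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=np.float64)
        if v.ndim != 3 or min(v.shape) < 1:
            raise ParameterError("phantom volume must be 3D")
        if self.voxel_size <= 0:
            raise ParameterError("voxel_size must be positive")
        if np.any(v < 0):
            raise ParameterError("attenuation coefficients must be nonnegative")
        object.__setattr__(self, "volume", v)

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * self.voxel_size for n in self.volume.shape)


@dataclass(frozen=True)
class ProjectionGeometry:
    """Cone-beam acquisition geometry.

    sdd/sod in mm (magnification = sdd/sod); pixel_pitch in mm; detector
    shape in pixels (rows, cols); i0 the unattenuated source intensity in
    ADU at the detector.
    """

    sdd: float = 1500.0
    sod: float = 1000.0
    pixel_pitch: float = 0.048
    detector_shape: tuple[int, int] = (512, 1024)
    i0: float = 3000.0

    def __post_init__(self) -> None:
        if not (0 < self.sod < self.sdd):
            raise ParameterError("require 0 < SOD < SDD")
        if self.pixel_pitch <= 0 or self.i0 <= 0:
            raise ParameterError("pixel_pitch and i0 must be positive")

    @property
    def magnification(self) -> float:
        return self.sdd / self.sod


#: Full-scale geometry: SDD 150 cm, SOD 100 cm, 48 um pixels, 512x1024 matrix.
FULL_SCALE_GEOMETRY = ProjectionGeometry()

#: Reduced geometry for fast runs: same SDD/SOD ratio, coarser 0.1 mm pixels
#: on a 256x512 matrix, pairing with a 150-voxel phantom.
DESK_SCALE_GEOMETRY = ProjectionGeometry(pixel_pitch=0.1, detector_shape=(256, 512))


@dataclass(frozen=True)
class DetectorProfile:
    """Everything the degradation pipeline needs to know about one detector."""

    name: str
    scintillator_thickness_um: float
    pixel_size_um: float
    sigma_lsf: float
    noise: NoiseModel
    adc_bits: int = 12
    matrix: tuple[int, int] = (512, 1024)

    def __post_init__(self) -> None:
        if self.adc_bits not in (12, 14, 16):
            raise ParameterError("adc_bits must be one of 12, 14, 16")
        if self.scintillator_thickness_um <= 0 or self.pixel_size_um <= 0:
            raise ParameterError("physical dimensions must be positive")

    @property
    def adc_max(self) -> float:
        return float(2**self.adc_bits - 1)


def load_detector_profiles() -> dict[str, DetectorProfile]:
    """Load the packaged thin/medium/thick detector profile family."""
    text = (
        importlib.resources.files("adaptpsf").joinpath("data/detectors.yaml").read_text()
    )
    raw = yaml.safe_load(text)
    out = {}
    for name, d in raw.items():
        out[name] = DetectorProfile(
            name=name,
            scintillator_thickness_um=d["scintillator_thickness_um"],
            pixel_size_um=d["pixel_size_um"],
            sigma_lsf=d["sigma_lsf"],
            noise=NoiseModel(alpha=d["alpha"], beta=d["beta"]),
            adc_bits=d["adc_bits"],
            matrix=tuple(d["matrix"]),
        )
    return out


# ---------------------------------------------------------------------------
# Phantoms and fixtures
# ---------------------------------------------------------------------------

# die pip layouts on the unit face, coordinates in (-1, 1)
_PIP_LAYOUT = {
    1: [(0.0, 0.0)],
    2: [(-0.5, -0.5), (0.5, 0.5)],
    3: [(-0.5, -0.5), (0.0, 0.0), (0.5, 0.5)],
    4: [(-0.5, -0.5), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.5)],
    5: [(-0.5, -0.5), (-0.5, 0.5), (0.0, 0.0), (0.5, -0.5), (0.5, 0.5)],
    6: [(-0.5, -0.5), (-0.5, 0.0), (-0.5, 0.5), (0.5, -0.5), (0.5, 0.0), (0.5, 0.5)],
}


def build_dice_phantom(
    n_voxels: int = 300,
    voxel_size: float = 0.1,
    mu_material: float = 0.0227,
    pip_radius_fraction: float = 0.1,
) -> Phantom3D:
    """Solid attenuating cube with spherical pip recesses arranged as die faces.

    The pips (zero-attenuation spheres centered on the cube faces, radius
    ``pip_radius_fraction`` of the edge length) give the projection internal
    edges at several depths. ``mu_material`` defaults to PMMA at an
    effective ~70 keV beam, 0.0227 /mm.
    """
    if n_voxels < 50:
        raise ParameterError("n_voxels must be >= 50")
    if mu_material <= 0:
        raise ParameterError("mu_material must be positive")
    n = n_voxels
    vol = np.full((n, n, n), mu_material, dtype=np.float64)
    edge = n * voxel_size
    r_pip = pip_radius_fraction * edge
    half = edge / 2.0

    ax = (np.arange(n) + 0.5) * voxel_size - half  # voxel centers, cube-centered
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")

    # opposite faces sum to 7, standard die
    faces = [
        (1, (X, Y, Z), -half),  # face at z = -half
        (6, (X, Y, Z), +half),
        (2, (X, Z, Y), -half),
        (5, (X, Z, Y), +half),
        (3, (Y, Z, X), -half),
        (4, (Y, Z, X), +half),
    ]
    for count, (A, B, C), c_pos in faces:
        for (pa, pb) in _PIP_LAYOUT[count]:
            ca, cb = pa * half * 0.9, pb * half * 0.9
            mask = (A - ca) ** 2 + (B - cb) ** 2 + (C - c_pos) ** 2 < r_pip**2
            vol[mask] = 0.0

    return Phantom3D(
        volume=vol, voxel_size=voxel_size, materials={"PMMA": mu_material, "air": 0.0}
    )


def project_phantom(phantom: Phantom3D, geom: ProjectionGeometry) -> np.ndarray:
    """Cone-beam Beer–Lambert projection of the phantom onto the detector.

    The source sits on the axis at the origin, the phantom is centered at
    depth SOD and the detector plane at SDD. For each detector pixel the
    attenuation line integral is accumulated by incremental parametric
    stepping at half-voxel depth steps with trilinear sampling of the
    volume; the pixel value is I0·exp(−L). Mono-energetic, no scatter.
    """
    vol = phantom.volume
    nz = vol.shape[2]
    half_extent = 0.5 * np.array(vol.shape) * phantom.voxel_size
    rows, cols = geom.detector_shape

    # detector pixel centers in mm, detector plane at z = SDD
    u = (np.arange(rows) - (rows - 1) / 2.0) * geom.pixel_pitch
    v = (np.arange(cols) - (cols - 1) / 2.0) * geom.pixel_pitch
    U, V = np.meshgrid(u, v, indexing="ij")

    z0, z1 = geom.sod - half_extent[2], geom.sod + half_extent[2]
    if z0 <= 0:
        raise ParameterError("phantom extends behind the source")
    dz = 0.5 * phantom.voxel_size
    z_samples = np.arange(z0 + dz / 2.0, z1, dz)

    # per-ray path-length element: dz stretched by the ray obliquity
    ds = dz * np.sqrt(1.0 + (U**2 + V**2) / geom.sdd**2)

    L = np.zeros((rows, cols))
    scale = 1.0 / phantom.voxel_size
    nx, ny = vol.shape[0], vol.shape[1]
    any_hit = False
    for z in z_samples:
        t = z / geom.sdd
        # containing-voxel lookup: the phantom is piecewise constant per
        # voxel, so indexing the voxel that holds each sample point keeps
        # slab path lengths exact to the stepping resolution
        ix = np.floor((U * t + half_extent[0]) * scale).astype(np.intp)
        iy = np.floor((V * t + half_extent[1]) * scale).astype(np.intp)
        iz = int((z - (geom.sod - half_extent[2])) * scale)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (0 <= iz < nz)
        mu = np.where(inside, vol[ix.clip(0, nx - 1), iy.clip(0, ny - 1), min(max(iz, 0), nz - 1)], 0.0)
        if not any_hit and mu.any():
            any_hit = True
        L += mu
    L *= ds
    if not any_hit and vol.max() > 0:
        warnings.warn("phantom not intersected by any ray: empty projection", stacklevel=2)
    return geom.i0 * np.exp(-L)


def generate_line_chart(
    frequencies: list[float] | None = None,
    pixel_pitch: float = 0.048,
    contrast: float = 2000.0,
    base: float = 500.0,
    group_height: int = 32,
    width: int = 512,
) -> np.ndarray:
    """Bar-pattern resolution chart: one band of vertical bars per frequency.

    Each group alternates ``base`` and ``base + contrast`` ADU at the
    requested spatial frequency (lp/mm); the default chart spans 20 groups
    from 0.6 to 5.0 lp/mm. The bar period in pixels is 1/(freq·pitch).

    Raises
    ------
    ParameterError
        If any frequency is at or above the detector Nyquist limit
        1/(2·pitch), where the bar pattern would alias.
    """
    if frequencies is None:
        frequencies = list(np.round(np.linspace(0.6, 5.0, 20), 3))
    nyquist = 1.0 / (2.0 * pixel_pitch)
    for f in frequencies:
        if f <= 0:
            raise ParameterError("frequencies must be positive")
        if f >= nyquist:
            raise ParameterError(
                f"frequency {f} lp/mm at or above Nyquist ({nyquist:.2f} lp/mm): aliasing"
            )
    x = np.arange(width)
    bands = []
    for f in frequencies:
        period_px = 1.0 / (f * pixel_pitch)
        phase = np.floor(2.0 * x / period_px).astype(int) % 2
        row = base + contrast * (phase == 0)
        bands.append(np.tile(row, (group_height, 1)))
    return np.vstack(bands).astype(np.float64)


def degrade_image(
    clean: np.ndarray,
    profile: DetectorProfile,
    seed: int,
) -> np.ndarray:
    """Detector forward model: PSF blur, then Poisson–Gaussian noise, then ADC clip.

    The clean (noise-free, unblurred) image is convolved with the Gaussian
    PSF of the profile's LSF width using replicate padding, noise of the
    profile's NLF is applied to the blurred signal, and the result is
    clipped to [0, 2^adc_bits − 1]. Fixed seed gives bit-identical output.
    """
    img = np.asarray(clean, dtype=np.float64)
    if np.any(img < 0):
        raise InputError("clean image must be nonnegative")
    if profile.sigma_lsf > 0:
        blurred = ndimage.gaussian_filter(img, profile.sigma_lsf, mode="nearest", truncate=4.0)
    else:
        blurred = img
    return synthesize_noise(blurred, profile.noise, seed=seed, clip_max=profile.adc_max)
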