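"""Full-reference and no-reference image-quality measures.

Implements the metric suite used to score candidate PSF widths and restored
radiographs:

* SSIM — windowed structural similarity combining luminance, contrast and
  structure terms with stabilizers C1=(k1·L)², C2=(k2·L)², C3=C2/2.
* FSIM — feature similarity combining phase-congruency (PC) and
  gradient-magnitude (GM) agreement, weighted by max(PC1, PC2).
* Phase congruency — contrast-invariant edge/line significance from a
  log-Gabor filter bank (multi-scale, multi-orientation).
* CNR — contrast-to-noise ratio between target and background ROIs.
* GM — mean gradient magnitude (Sobel/Prewitt/Scharr), a scalar sharpness
  index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InputError, NumericError, ParameterError

__all__ = [
    "SSIMConfig",
    "FSIMConfig",
    "ROISpec",
    "ssim",
    "fsim",
    "phase_congruency_map",
    "cnr",
    "gradient_magnitude",
]

_EPS = 1e-10


@dataclass(frozen=True)
class SSIMConfig:
    """SSIM stabilizers, dynamic range, window and component exponents.

    k1/k2 are the usual 0.01/0.03 fractions of the dynamic range L (ADU;
    4095 for a 12-bit detector, or 1 for unit-normalized data). Local
    statistics use an 11x11 Gaussian-tapered window with taper sigma 1.5,
    the metric's canonical form. Component exponents default to 1.
    """

    k1: float = 0.01
    k2: float = 0.03
    dynamic_range: float = 4095.0
    window_size: int = 11
    window_sigma: float = 1.5
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ParameterError("k1 and k2 must be positive")
        if self.dynamic_range <= 0:
            raise ParameterError("dynamic_range must be positive")
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ParameterError("window_size must be odd and >= 3")


@dataclass(frozen=True)
class FSIMConfig:
    """FSIM stability constants and the log-Gabor bank specification.

    T1/T2 stabilize the PC and GM similarity terms on inputs rescaled to the
    8-bit range; the bank defaults (4 scales, 4 orientations, minimum
    wavelength 6 px, scale multiplier 2, log-Gabor bandwidth parameter
    sigma_f = 0.55) follow standard FSIM practice.
    """

    t1: float = 0.85
    t2: float = 160.0
    alpha: float = 1.0
    beta: float = 1.0
    n_scales: int = 4
    n_orientations: int = 4
    min_wavelength: float = 6.0
    scale_multiplier: float = 2.0
    sigma_f: float = 0.55
    noise_k: float = 2.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ParameterError("T1 and T2 must be positive")
        if self.n_scales < 1 or self.n_orientations < 1:
            raise ParameterError("need at least one scale and orientation")


@dataclass(frozen=True)
class ROISpec:
    """Target and background rectangles, each (row, col, height, width)."""

    target: tuple[int, int, int, int]
    background: list[tuple[int, int, int, int]] = field(default_factory=list)

    def validate(self, shape: tuple[int, int]) -> None:
        for rect in [self.target, *self.background]:
            r, c, h, w = rect
            if r < 0 or c < 0 or h <= 0 or w <= 0 or r + h > shape[0] or c + w > shape[1]:
                raise InputError(f"ROI {rect} does not fit inside image of shape {shape}")


def _extract(img: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    r, c, h, w = rect
    return img[r : r + h, c : c + w]


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def _local_stats(x, y, cfg):
    truncate = ((cfg.window_size - 1) // 2) / cfg.window_sigma
    blur = lambda a: ndimage.gaussian_filter(a, cfg.window_sigma, truncate=truncate)
    mx, my = blur(x), blur(y)
    vxx = blur(x * x) - mx * mx
    vyy = blur(y * y) - my * my
    vxy = blur(x * y) - mx * my
    return mx, my, np.clip(vxx, 0, None), np.clip(vyy, 0, None), vxy


def ssim(x: np.ndarray, y: np.ndarray, cfg: SSIMConfig | None = None) -> float:
    """Mean structural similarity between two images.

    Local means, variances and cross-covariance are computed under the
    Gaussian window; with the default unit exponents and C3=C2/2 the local
    score reduces to the familiar two-factor form

        ((2 μx μy + C1)(2 σxy + C2)) / ((μx²+μy²+C1)(σx²+σy²+C2)).

    The map is cropped by the window half-size before averaging so that
    boundary-padding never enters the score.
    """
    cfg = cfg or SSIMConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2:
        raise InputError(f"images must be 2D with matching shapes, got {x.shape} vs {y.shape}")
    c1 = (cfg.k1 * cfg.dynamic_range) ** 2
    c2 = (cfg.k2 * cfg.dynamic_range) ** 2
    c3 = c2 / 2.0
    mx, my, vxx, vyy, vxy = _local_stats(x, y, cfg)

    if cfg.alpha == 1.0 and cfg.beta == 1.0 and cfg.gamma == 1.0:
        smap = ((2 * mx * my + c1) * (2 * vxy + c2)) / (
            (mx * mx + my * my + c1) * (vxx + vyy + c2)
        )
    else:
        sx, sy = np.sqrt(vxx), np.sqrt(vyy)
        lum = (2 * mx * my + c1) / (mx * mx + my * my + c1)
        con = (2 * sx * sy + c2) / (vxx + vyy + c2)
        stru = (vxy + c3) / (sx * sy + c3)
        powed = lambda a, p: np.sign(a) * np.abs(a) ** p
        smap = powed(lum, cfg.alpha) * powed(con, cfg.beta) * powed(stru, cfg.gamma)

    pad = (cfg.window_size - 1) // 2
    return float(smap[pad:-pad, pad:-pad].mean())


# ---------------------------------------------------------------------------
# Phase congruency (log-Gabor bank)
# ---------------------------------------------------------------------------

def _log_gabor_bank(shape, cfg: FSIMConfig):
    """Frequency-domain log-Gabor filters, one per (scale, orientation)."""
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(fx, fy)
    radius[0, 0] = 1.0  # avoid log(0); the DC gain is forced to zero below
    theta = np.arctan2(-fy, fx)

    # low-pass envelope keeps the largest-scale filter from wrapping at Nyquist
    lowpass = 1.0 / (1.0 + (radius / 0.45) ** 30)

    radial = []
    for s in range(cfg.n_scales):
        wavelength = cfg.min_wavelength * cfg.scale_multiplier**s
        f0 = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(cfg.sigma_f) ** 2))
        lg *= lowpass
        lg[0, 0] = 0.0
        radial.append(lg)

    angular = []
    d_theta_sigma = np.pi / cfg.n_orientations / 1.2
    for o in range(cfg.n_orientations):
        angle = o * np.pi / cfg.n_orientations
        ds = np.sin(theta) * np.cos(angle) - np.cos(theta) * np.sin(angle)
        dc = np.cos(theta) * np.cos(angle) + np.sin(theta) * np.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        angular.append(np.exp(-(dtheta**2) / (2.0 * d_theta_sigma**2)))
    return radial, angular


def phase_congruency_map(x: np.ndarray, cfg: FSIMConfig | None = None) -> np.ndarray:
    """Phase-congruency field in [0, 1].

    Measures how consistently the local Fourier components are in phase
    across scales — maximal on step edges and lines regardless of their
    contrast, near zero on smooth regions. Per orientation, complex
    log-Gabor responses are summed over scales; the phase-deviation-weighted
    energy, minus a Rayleigh-model noise floor estimated from the
    smallest-scale amplitudes, is normalized by the total amplitude. The
    measure is invariant to affine intensity rescaling (the noise floor
    scales with the signal) and a constant image maps to zero.
    """
    cfg = cfg or FSIMConfig()
    img = np.asarray(x, dtype=np.float64)
    if img.ndim != 2:
        raise InputError("phase congruency expects a 2D image")
    F = np.fft.fft2(img)
    radial, angular = _log_gabor_bank(img.shape, cfg)

    total_energy = np.zeros(img.shape)
    total_amplitude = np.zeros(img.shape)
    for ang in angular:
        sum_e = np.zeros(img.shape)
        sum_o = np.zeros(img.shape)
        sum_an = np.zeros(img.shape)
        amp_smallest = None
        for s, rad in enumerate(radial):
            resp = np.fft.ifft2(F * (rad * ang))
            e, o = resp.real, resp.imag
            an = np.hypot(e, o)
            sum_e += e
            sum_o += o
            sum_an += an
            if s == 0:
                amp_smallest = an
        xe = np.hypot(sum_e, sum_o) + _EPS
        mean_e, mean_o = sum_e / xe, sum_o / xe
        # sum over scales of An·cos(phi - phibar) - |An·sin(phi - phibar)|,
        # folded into the accumulated even/odd parts per Kovesi
        energy = np.zeros(img.shape)
        for rad in radial:
            resp = np.fft.ifft2(F * (rad * ang))
            e, o = resp.real, resp.imag
            energy += e * mean_e + o * mean_o - np.abs(e * mean_o - o * mean_e)
        # Rayleigh noise floor from the smallest-scale amplitude distribution
        tau = np.median(amp_smallest) / np.sqrt(np.log(4.0))
        m = cfg.scale_multiplier
        total_tau = tau * (1.0 - (1.0 / m) ** cfg.n_scales) / (1.0 - 1.0 / m)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        threshold = noise_mean + cfg.noise_k * noise_sigma
        total_energy += np.clip(energy - threshold, 0.0, None)
        total_amplitude += sum_an
    return total_energy / (total_amplitude + _EPS)


# ---------------------------------------------------------------------------
# Gradient magnitude
# ---------------------------------------------------------------------------

_OPERATORS = {
    "sobel": np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]]),
    "prewitt": np.array([[1.0, 0.0, -1.0], [1.0, 0.0, -1.0], [1.0, 0.0, -1.0]]),
    "scharr": np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0,
}


def gradient_magnitude(
    img: np.ndarray, operator: str = "sobel"
) -> tuple[np.ndarray, float]:
    """Per-pixel gradient magnitude and its image mean (the scalar GM score).

    GM(x) = sqrt((I⊗f_h)² + (I⊗f_v)²) for the chosen derivative operator
    pair; higher mean GM means a sharper image.
    """
    if operator not in _OPERATORS:
        raise ParameterError(
            f"unknown operator {operator!r}; choose from {sorted(_OPERATORS)}"
        )
    im = np.asarray(img, dtype=np.float64)
    if im.ndim != 2:
        raise InputError("gradient_magnitude expects a 2D image")
    fh = _OPERATORS[operator]
    gx = ndimage.convolve(im, fh, mode="reflect")
    gy = ndimage.convolve(im, fh.T, mode="reflect")
    gmap = np.hypot(gx, gy)
    return gmap, float(gmap.mean())


# ---------------------------------------------------------------------------
# FSIM
# ---------------------------------------------------------------------------

def _rescale_pair_8bit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map both images with one affine transform onto [0, 255]."""
    lo = min(float(x.min()), float(y.min()))
    hi = max(float(x.max()), float(y.max()))
    span = hi - lo
    if span <= 0:
        return np.zeros_like(x), np.zeros_like(y)
    return (x - lo) * (255.0 / span), (y - lo) * (255.0 / span)


def _fsim_features(img: np.ndarray, cfg: FSIMConfig) -> tuple[np.ndarray, np.ndarray]:
    pc = phase_congruency_map(img, cfg)
    gx = ndimage.convolve(img, _OPERATORS["scharr"], mode="reflect")
    gy = ndimage.convolve(img, _OPERATORS["scharr"].T, mode="reflect")
    return pc, np.hypot(gx, gy)


def fsim(x: np.ndarray, y: np.ndarray, cfg: FSIMConfig | None = None) -> float:
    """Feature similarity between two images, in [0, 1].

    Phase-congruency and Scharr gradient-magnitude maps of both inputs
    (jointly rescaled to the 8-bit range) are compared point-wise with
    stabilized ratio terms S_PC and S_G; their product is averaged with the
    weighting field PC(x) = max(PC1(x), PC2(x)), which emphasizes locations
    either image considers perceptually significant and makes the score
    symmetric in its arguments.
    """
    cfg = cfg or FSIMConfig()
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 2:
        raise InputError(f"images must be 2D with matching shapes, got {x.shape} vs {y.shape}")
    xs, ys = _rescale_pair_8bit(x, y)
    pc1, gm1 = _fsim_features(xs, cfg)
    pc2, gm2 = _fsim_features(ys, cfg)

    s_pc = (2.0 * pc1 * pc2 + cfg.t1) / (pc1**2 + pc2**2 + cfg.t1)
    s_g = (2.0 * gm1 * gm2 + cfg.t2) / (gm1**2 + gm2**2 + cfg.t2)
    weight = np.maximum(pc1, pc2)
    sim = (s_pc**cfg.alpha) * (s_g**cfg.beta)
    denom = weight.sum()
    if denom <= _EPS:
        # no phase structure anywhere (e.g. two constant images): fall back
        # to the unweighted mean similarity
        return float(sim.mean())
    return float((sim * weight).sum() / denom)


# ---------------------------------------------------------------------------
# CNR
# ---------------------------------------------------------------------------

def cnr(img: np.ndarray, rois: ROISpec | list[ROISpec]) -> float:
    """Contrast-to-noise ratio (μ_T − μ_B) / sqrt(σ_T² + σ_B²).

    A list of ROI specs is evaluated per-spec and averaged, matching the
    practice of quoting a mean CNR over several target regions.
    """
    im = np.asarray(img, dtype=np.float64)
    if isinstance(rois, ROISpec):
        rois = [rois]
    if not rois:
        raise ParameterError("at least one ROI spec required")
    scores = []
    for spec in rois:
        spec.validate(im.shape)
        t = _extract(im, spec.target)
        if spec.background:
            b = np.concatenate([_extract(im, r).ravel() for r in spec.background])
        else:
            raise InputError("ROI spec needs at least one background rectangle")
        var_sum = t.var(ddof=1) + b.var(ddof=1)
        if var_sum <= 0:
            raise NumericError("undefined CNR: zero variance in both ROIs")
        scores.append((t.mean() - b.mean()) / np.sqrt(var_sum))
    return float(np.mean(scores))
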