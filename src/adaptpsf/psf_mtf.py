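"""Gaussian PSF/LSF models, MTF computation and inversion, slit-based LSF measurement.

The detector blur is modeled as an isotropic 2D Gaussian point-spread function

    PSF(m, n) ∝ exp(-(m² + n²) / (2σ²)),

whose line-spread function (the 1D marginal) is Gaussian with the same σ and
whose modulation transfer function is the magnitude of the Fourier transform
of the LSF,

    MTF(u) = exp(-2π² σ² u²),   u in cycles/pixel.

σ can therefore be recovered from a measured MTF by a least-squares fit that
is linear in u² after taking logs, and measured directly from a tilted-slit
image by the classical presampled-LSF oversampling technique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DetectionError, NumericError, ParameterError

__all__ = [
    "GaussianPSFModel",
    "MTFCurve",
    "LSFProfile",
    "gaussian_psf_kernel",
    "mtf_from_sigma",
    "sigma_from_mtf_fit",
    "lsf_from_slit_image",
    "gaussian_fwhm",
]

#: FWHM of a unit-σ Gaussian, 2·sqrt(2·ln 2).
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class GaussianPSFModel:
    """Isotropic Gaussian PSF: blur width plus its discretized, unit-sum kernel.

    Attributes
    ----------
    sigma : float
        Blur standard deviation in pixels.
    support_halfwidth : int
        Kernel half-size; the kernel is square with odd side
        ``2 * support_halfwidth + 1``.
    kernel : numpy.ndarray
        Nonnegative weights summing to 1, symmetric under flips and
        90° rotation.
    """

    sigma: float
    support_halfwidth: int
    kernel: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ParameterError(f"sigma must be positive, got {self.sigma}")
        k = np.asarray(self.kernel, dtype=np.float64)
        side = 2 * self.support_halfwidth + 1
        if k.shape != (side, side):
            raise ParameterError(
                f"kernel shape {k.shape} inconsistent with half-width {self.support_halfwidth}"
            )
        if np.any(k < 0):
            raise ParameterError("kernel weights must be nonnegative")
        if abs(float(k.sum()) - 1.0) > 1e-12:
            raise ParameterError("kernel must sum to 1 within 1e-12")

    @property
    def fwhm(self) -> float:
        """Full width at half maximum of the continuous profile, in pixels."""
        return FWHM_FACTOR * self.sigma


@dataclass(frozen=True)
class MTFCurve:
    """Modulation transfer function sampled on a frequency grid.

    ``frequencies`` are in cycles/pixel (use :meth:`to_lp_per_mm` for lp/mm
    given a pixel pitch); ``values`` are modulation factors in [0, 1] with
    ``values[0] == 1`` after normalization when the grid starts at DC.
    """

    frequencies: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if f.shape != v.shape or f.ndim != 1:
            raise ParameterError("frequencies and values must be matching 1D arrays")
        if np.any(f < 0):
            raise ParameterError("frequencies must be nonnegative")
        if np.any(np.diff(f) <= 0):
            raise ParameterError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    def to_lp_per_mm(self, pixel_pitch_mm: float) -> np.ndarray:
        """Convert the frequency axis from cycles/pixel to lp/mm."""
        if pixel_pitch_mm <= 0:
            raise ParameterError("pixel pitch must be positive")
        return self.frequencies / pixel_pitch_mm


@dataclass(frozen=True)
class LSFProfile:
    """Oversampled line-spread function from a slit measurement.

    positions are subpixel distances (pixels) to the slit axis; values are
    baseline-subtracted, area-normalized samples; bin_width is the
    oversampling bin size in pixels.
    """

    positions: np.ndarray
    values: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=np.float64)
        v = np.asarray(self.values, dtype=np.float64)
        if p.shape != v.shape or p.ndim != 1:
            raise ParameterError("positions and values must be matching 1D arrays")
        object.__setattr__(self, "positions", p)
        object.__setattr__(self, "values", v)

    def fit_sigma(self) -> float:
        """Gaussian width of the profile via moment matching (robust to tails)."""
        w = np.clip(self.values, 0, None)
        total = w.sum()
        if total <= 0:
            raise NumericError("LSF profile has no positive mass")
        mu = float((self.positions * w).sum() / total)
        var = float(((self.positions - mu) ** 2 * w).sum() / total)
        return float(np.sqrt(max(var, 0.0)))


def gaussian_psf_kernel(sigma: float, truncation_multiple: float = 4.0) -> GaussianPSFModel:
    """Discretize the isotropic Gaussian PSF on an odd square support.

    The kernel is sampled at integer pixel offsets out to
    ``ceil(truncation_multiple * sigma)`` and renormalized to unit sum
    (truncation at 4σ loses < 1e-4 of the mass before renormalization).

    Parameters
    ----------
    sigma : float
        Blur width in pixels, > 0.
    truncation_multiple : float
        Support half-width in units of sigma, >= 2.

    Returns
    -------
    GaussianPSFModel
    """
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    if truncation_multiple < 2:
        raise ParameterError("truncation_multiple must be >= 2")
    half = int(np.ceil(truncation_multiple * sigma))
    half = max(half, 1)
    offsets = np.arange(-half, half + 1, dtype=np.float64)
    profile = np.exp(-(offsets**2) / (2.0 * sigma**2))
    kernel = np.outer(profile, profile)
    kernel /= kernel.sum()
    return GaussianPSFModel(sigma=float(sigma), support_halfwidth=half, kernel=kernel)


def identity_kernel() -> GaussianPSFModel:
    """A 1x1-support delta kernel (no blur); sigma is a nominal tiny value."""
    k = np.zeros((3, 3))
    k[1, 1] = 1.0
    return GaussianPSFModel(sigma=1e-12, support_halfwidth=1, kernel=k)


def mtf_from_sigma(sigma: float, frequencies: np.ndarray) -> MTFCurve:
    """MTF of a Gaussian LSF: exp(-2π²σ²u²) on the given grid (cycles/pixel)."""
    if sigma <= 0:
        raise ParameterError(f"sigma must be positive, got {sigma}")
    f = np.asarray(frequencies, dtype=np.float64)
    if np.any(f < 0):
        raise ParameterError("frequencies must be nonnegative")
    values = np.exp(-2.0 * np.pi**2 * sigma**2 * f**2)
    return MTFCurve(frequencies=f, values=values)


def sigma_from_mtf_fit(curve: MTFCurve, min_value: float = 0.01) -> float:
    """Recover σ from a measured MTF by least squares on the Gaussian model.

    The Gaussian MTF is linear in u² after a log transform,
    ``log MTF = -2π²σ²u²``, so the fit is a one-parameter linear regression
    through the origin restricted to samples with modulation above
    ``min_value`` (the deep tail is noise-dominated in measured curves).

    Raises
    ------
    NumericError
        If fewer than 2 usable samples remain or the curve carries no decay.
    """
    u = curve.frequencies
    v = curve.values
    mask = (v > min_value) & (v <= 1.0 + 1e-9) & (u > 0)
    if mask.sum() < 2:
        raise NumericError("not enough usable MTF samples for a fit")
    x = u[mask] ** 2
    y = np.log(np.clip(v[mask], 1e-300, None))
    denom = float((x * x).sum())
    slope = float((x * y).sum() / denom)
    if slope >= 0 or not np.isfinite(slope):
        raise NumericError("degenerate MTF curve: no measurable decay")
    sigma2 = -slope / (2.0 * np.pi**2)
    return float(np.sqrt(sigma2))


def lsf_from_slit_image(
    image: np.ndarray,
    tilt_deg: float | None = None,
    bin_width: float = 0.1,
    contrast_threshold: float = 0.1,
) -> LSFProfile:
    """Presampled LSF from a tilted-slit radiograph.

    The slit is assumed bright on a dark background and approximately
    vertical, tilted by a small angle (1.5°–3° recommended) so that
    successive rows sample the slit at different subpixel phases. Per-row
    intensity centroids are regressed to a straight line; every pixel's
    signed distance to that line, weighted by its baseline-subtracted
    intensity, is accumulated into bins of width ``bin_width`` to form the
    oversampled profile, which is then area-normalized.

    Parameters
    ----------
    image : ndarray
        2D slit image.
    tilt_deg : float, optional
        Nominal tilt; informational only (the tilt is re-estimated from the
        centroid regression).
    bin_width : float
        Oversampling bin size in pixels.
    contrast_threshold : float
        Minimum (peak - median) / peak contrast for slit detection.

    Raises
    ------
    DetectionError
        If no sufficiently contrasted slit is found.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ParameterError("slit image must be 2D")
    if bin_width <= 0:
        raise ParameterError("bin_width must be positive")

    baseline = float(np.median(img))
    peak = float(img.max())
    if peak <= 0 or (peak - baseline) / max(peak, 1e-12) < contrast_threshold:
        raise DetectionError("no slit detected: peak contrast below threshold")

    work = np.clip(img - baseline, 0.0, None)
    rows, cols = img.shape
    col_idx = np.arange(cols, dtype=np.float64)

    row_mass = work.sum(axis=1)
    usable = row_mass > 0.05 * row_mass.max()
    if usable.sum() < 4:
        raise DetectionError("no slit detected: too few rows with signal")
    centroids = (work[usable] * col_idx).sum(axis=1) / row_mass[usable]
    r = np.arange(rows, dtype=np.float64)[usable]

    # straight-line slit axis col = a*row + b
    a, b = np.polyfit(r, centroids, 1)

    # signed perpendicular distance of every pixel to the slit axis
    rr, cc = np.meshgrid(np.arange(rows, dtype=np.float64), col_idx, indexing="ij")
    dist = (cc - (a * rr + b)) / np.sqrt(1.0 + a * a)

    keep = np.broadcast_to(usable[:, None], work.shape)
    d = dist[keep]
    w = work[keep]

    lo = np.floor(d.min() / bin_width) * bin_width
    hi = np.ceil(d.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    hist, edges = np.histogram(d, bins=edges, weights=w)
    counts, _ = np.histogram(d, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    filled = counts > 0
    values = np.zeros_like(hist)
    values[filled] = hist[filled] / counts[filled]

    # residual baseline from the outermost bins, then area-normalize
    n_tail = max(2, int(0.05 * filled.sum()))
    tail_vals = np.concatenate([values[filled][:n_tail], values[filled][-n_tail:]])
    values = np.clip(values - float(np.median(tail_vals)), 0.0, None)
    area = values.sum() * bin_width
    if area <= 0:
        raise DetectionError("slit profile collapsed to zero after baseline subtraction")
    values = values / area

    return LSFProfile(positions=centers, values=values, bin_width=float(bin_width))
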