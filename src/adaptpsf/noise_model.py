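"""Poisson–Gaussian detector noise: synthesis and noise-level-function estimation.

The pixel noise of an indirect-conversion flat-panel detector is modeled as a
signal-dependent Poisson–Gaussian mixture: at clean signal level x (ADU) the
noise standard deviation is

    η(x) = sqrt(α·x + β²),

with α the Poisson gain (quantum noise, variance per ADU of signal) and β the
electronic Gaussian standard deviation in ADU. The variance-vs-mean line
v = α·m + β² is the detector's noise level function (NLF); its parameters are
estimated from uniform (flat-field) frames by a robust mean–variance
regression over image blocks, screening out non-uniform blocks with a
Kendall-τ whiteness test against one-pixel-shifted neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InputError, NumericError, ParameterError

__all__ = ["NoiseModel", "NLFEstimate", "synthesize_noise", "estimate_nlf"]


@dataclass(frozen=True)
class NoiseModel:
    """Poisson–Gaussian mixture parameters.

    alpha : Poisson gain (dimensionless, variance per ADU of signal), >= 0.
    beta : Gaussian standard deviation in ADU, >= 0.
    mode : 'gaussian-approx' draws clean + η(x)·δ with δ ~ N(0,1);
        'exact-mixture' draws α·Poisson(clean/α) + N(0, β²).
    """

    alpha: float
    beta: float
    mode: str = "gaussian-approx"

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ParameterError("alpha and beta must be nonnegative")
        if self.mode not in ("gaussian-approx", "exact-mixture"):
            raise ParameterError(f"unknown noise mode {self.mode!r}")

    @property
    def is_identity(self) -> bool:
        return self.alpha == 0 and self.beta == 0

    def std_at(self, signal: np.ndarray | float) -> np.ndarray | float:
        """Noise standard deviation η at the given clean signal level(s)."""
        return np.sqrt(self.alpha * np.asarray(signal, dtype=np.float64) + self.beta**2)


@dataclass(frozen=True)
class NLFEstimate:
    """Result of the mean–variance NLF fit.

    alpha_hat/beta_hat are the fitted slope and sqrt of the (floored)
    intercept; block_means/block_variances are the per-block statistics that
    survived the whiteness screen.
    """

    alpha_hat: float
    beta_hat: float
    block_means: np.ndarray = field(repr=False)
    block_variances: np.ndarray = field(repr=False)
    n_blocks_kept: int = 0
    n_blocks_total: int = 0


def synthesize_noise(
    clean: np.ndarray,
    model: NoiseModel,
    seed: int,
    clip_max: float | None = 4095.0,
) -> np.ndarray:
    """Apply Poisson–Gaussian noise to a clean image.

    In gaussian-approx mode (the default, and the form the NLF is fitted to)
    the output is clean + η(clean)·δ with δ standard normal. exact-mixture
    draws a true Poisson variate with mean clean/α, scales by α, and adds
    Gaussian read noise. The result is clipped to [0, clip_max] (the ADC
    range; pass None to disable clipping). Identical seeds give identical
    output.
    """
    img = np.asarray(clean, dtype=np.float64)
    if np.any(img < 0):
        raise InputError("clean image must be nonnegative")
    if model.is_identity:
        out = img.copy()
    else:
        rng = np.random.default_rng(seed)
        if model.mode == "gaussian-approx":
            eta = model.std_at(img)
            out = img + eta * rng.standard_normal(img.shape)
        else:
            if model.alpha > 0:
                out = model.alpha * rng.poisson(img / model.alpha).astype(np.float64)
            else:
                out = img.copy()
            if model.beta > 0:
                out = out + model.beta * rng.standard_normal(img.shape)
    if clip_max is not None:
        out = np.clip(out, 0.0, clip_max)
    else:
        out = np.clip(out, 0.0, None)
    return out


def _kendall_tau_whiteness(block: np.ndarray) -> float:
    """Kendall τ between block pixels and their one-pixel-shifted neighbors.

    For white (i.i.d.) noise on a uniform patch the shifted pairs are
    exchangeable and τ ≈ 0; structure (gradients, edges) induces positive
    rank correlation. The horizontal and vertical τ are averaged.
    """
    th = stats.kendalltau(block[:, :-1].ravel(), block[:, 1:].ravel()).statistic
    tv = stats.kendalltau(block[:-1, :].ravel(), block[1:, :].ravel()).statistic
    vals = [t for t in (th, tv) if np.isfinite(t)]
    return float(np.mean(vals)) if vals else 0.0


def _tau_critical(n_pairs: int, p: float) -> float:
    """Two-sided critical |τ| at significance p under the null (normal approx)."""
    z = stats.norm.ppf(1.0 - p / 2.0)
    return float(z * np.sqrt(2.0 * (2.0 * n_pairs + 5.0) / (9.0 * n_pairs * (n_pairs - 1.0))))


def _lad_line_fit(x: np.ndarray, y: np.ndarray, n_iter: int = 50) -> tuple[float, float]:
    """Least-absolute-deviation straight-line fit via IRLS.

    Returns (slope, intercept). LAD keeps outlier blocks (residual structure
    that slipped past the whiteness screen) from tilting the NLF line.
    """
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    for _ in range(n_iter):
        resid = y - A @ coef
        w = 1.0 / np.maximum(np.abs(resid), 1e-8)
        Aw = A * w[:, None]
        new, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
        if np.allclose(new, coef, rtol=1e-10, atol=1e-12):
            coef = new
            break
        coef = new
    return float(coef[0]), float(coef[1])


def estimate_nlf(
    flats: list[np.ndarray],
    block_size: int = 16,
    uniformity_p: float = 0.01,
) -> NLFEstimate:
    """Estimate the Poisson–Gaussian NLF from flat-field frames.

    Each frame is tiled into ``block_size``-square blocks. Blocks whose
    Kendall-τ against one-pixel-shifted neighbors exceeds the two-sided
    critical value at significance ``uniformity_p`` are discarded as
    non-uniform; surviving blocks contribute a (mean, unbiased variance)
    pair, and a least-absolute-deviation line fit of variance against mean
    yields alpha_hat (slope, floored at 0 with a warning) and beta_hat
    (sqrt of the intercept, floored at 0).

    Parameters
    ----------
    flats : list of 2D arrays
        Uniform-exposure frames; at least 3 distinct mean levels are needed
        to separate slope from intercept.
    block_size : int
        Block side in pixels, >= 8.
    uniformity_p : float
        Significance level of the whiteness screen.
    """
    if block_size < 8:
        raise ParameterError("block_size must be >= 8")
    if not flats:
        raise InputError("no flat frames supplied")
    level_means = [float(np.mean(f)) for f in flats]
    if len(np.unique(np.round(level_means, 1))) < 3:
        raise InputError("need flats at >= 3 distinct mean levels")

    n_pairs = block_size * (block_size - 1)
    tau_crit = _tau_critical(n_pairs, uniformity_p)

    means, variances = [], []
    n_total = 0
    for frame in flats:
        img = np.asarray(frame, dtype=np.float64)
        if img.ndim != 2:
            raise InputError("flat frames must be 2D")
        nr = img.shape[0] // block_size
        nc = img.shape[1] // block_size
        for i in range(nr):
            for j in range(nc):
                blk = img[
                    i * block_size : (i + 1) * block_size,
                    j * block_size : (j + 1) * block_size,
                ]
                n_total += 1
                if abs(_kendall_tau_whiteness(blk)) > tau_crit:
                    continue
                means.append(float(blk.mean()))
                variances.append(float(blk.var(ddof=1)))

    if len(means) < 3:
        raise NumericError(
            f"insufficient data: only {len(means)} uniform blocks survived the screen"
        )
    m = np.asarray(means)
    v = np.asarray(variances)
    slope, intercept = _lad_line_fit(m, v)
    if slope < 0:
        import warnings

        warnings.warn("fitted NLF slope is negative; flooring alpha_hat at 0", stacklevel=2)
        slope = 0.0
    beta_hat = float(np.sqrt(max(intercept, 0.0)))
    return NLFEstimate(
        alpha_hat=slope,
        beta_hat=beta_hat,
        block_means=m,
        block_variances=v,
        n_blocks_kept=len(m),
        n_blocks_total=n_total,
    )
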