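"""Non-blind deconvolution engines: TV-regularized splitting, Wiener, Richardson–Lucy.

The workhorse is the total-variation-regularized solver

    f* = argmin_f  ||PSF ⊗ f − g||₂² + λ ||∇f||₁,

minimized by augmented-Lagrangian variable splitting (split-Bregman style):
frequency-domain quadratic solves for the image variables, soft shrinkage on
the split gradient, and scaled multiplier updates. The ℓ1
gradient penalty restores sharpness while suppressing the ringing and noise
amplification of unregularized inverse filtering; λ balances fidelity
against smoothness (λ = 0.01 is the working default for unit-normalized
radiographs).

Classic Wiener filtering and Richardson–Lucy iterations are provided as the
reference engines the TV solver is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, ParameterError
from .psf_mtf import GaussianPSFModel

__all__ = [
    "TVRestorationConfig",
    "WienerConfig",
    "RLConfig",
    "TVResult",
    "deconvolve_tv",
    "wiener_deconvolve",
    "richardson_lucy",
    "edge_taper",
    "psf_to_otf",
]


@dataclass(frozen=True)
class TVRestorationConfig:
    """TV solver settings.

    lam is the regularization weight λ (default 0.01, tuned for images
    normalized to [0, 1]); tolerance is the relative-iterate-change stopping
    threshold (default 1e-4); penalty is the splitting weight ρ (default
    max(10·λ, 0.1)); tv_flavor 'anisotropic' penalizes
    |∂x f| + |∂y f| (the printed ℓ1 of the gradient), 'isotropic' the
    Euclidean gradient norm.
    """

    lam: float = 0.01
    tolerance: float = 1e-4
    max_iterations: int = 300
    penalty: float | None = None
    tv_flavor: str = "anisotropic"

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ParameterError("lambda must be positive")
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.tv_flavor not in ("anisotropic", "isotropic"):
            raise ParameterError(f"unknown tv_flavor {self.tv_flavor!r}")

    @property
    def rho(self) -> float:
        # scale with lambda but keep a floor: an under-penalized splitting
        # oscillates and transfers deblurred detail into f too slowly
        return self.penalty if self.penalty is not None else max(10.0 * self.lam, 0.1)


@dataclass(frozen=True)
class WienerConfig:
    """K is the Wiener noise-to-signal constant (K=0 is the pure inverse filter)."""

    k: float = 1e-3
    edge_taper: bool = True

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ParameterError("Wiener constant K must be nonnegative")


@dataclass(frozen=True)
class RLConfig:
    """Richardson–Lucy iteration count and ratio-denominator floor."""

    n_iterations: int = 20
    floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if self.floor <= 0:
            raise ParameterError("floor must be positive")


@dataclass(frozen=True)
class TVResult:
    """Restored image plus solver diagnostics."""

    image: np.ndarray = field(repr=False)
    converged: bool = False
    n_iterations: int = 0
    objective_history: np.ndarray = field(repr=False, default=None)


def _check_psf(psf: GaussianPSFModel | np.ndarray) -> np.ndarray:
    kernel = psf.kernel if isinstance(psf, GaussianPSFModel) else np.asarray(psf, float)
    if abs(float(kernel.sum()) - 1.0) > 1e-8 or np.any(kernel < 0):
        raise ParameterError("PSF kernel must be nonnegative and sum to 1")
    return kernel


def psf_to_otf(kernel: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-pad a centered kernel to ``shape`` and FFT it with the center at (0,0)."""
    if kernel.shape[0] > shape[0] or kernel.shape[1] > shape[1]:
        raise ParameterError("PSF kernel larger than the image")
    pad = np.zeros(shape)
    kh, kw = kernel.shape
    pad[:kh, :kw] = kernel
    pad = np.roll(pad, (-(kh // 2), -(kw // 2)), axis=(0, 1))
    return np.fft.fft2(pad)


def edge_taper(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Blend image borders toward their blurred version to damp FFT wrap-around.

    The blend weight ramps from 0 at the border to 1 in the interior over
    the kernel half-support, following the autocorrelation of the kernel's
    axis projections (the classical edge-taper construction).
    """
    def ramp(n: int, proj: np.ndarray) -> np.ndarray:
        acorr = np.correlate(proj, proj, mode="full")
        acorr = acorr / acorr.max()
        w = np.ones(n)
        half = min(len(acorr) // 2, (n - 1) // 2)
        rise = 1.0 - acorr[len(acorr) // 2 + 1 :][:half][::-1]
        w[:half] = rise
        w[n - half :] = rise[::-1]
        return w

    alpha = np.outer(ramp(img.shape[0], kernel.sum(axis=1)), ramp(img.shape[1], kernel.sum(axis=0)))
    otf = psf_to_otf(kernel, img.shape)
    blurred = np.real(np.fft.ifft2(np.fft.fft2(img) * otf))
    return alpha * img + (1.0 - alpha) * blurred


def _shrink(v: np.ndarray, thresh: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - thresh, 0.0)


def deconvolve_tv(
    degraded: np.ndarray,
    psf: GaussianPSFModel | np.ndarray,
    cfg: TVRestorationConfig | None = None,
    full_output: bool = False,
) -> np.ndarray | TVResult:
    """TV-regularized non-blind deconvolution by augmented-Lagrangian splitting.

    Minimizes ``||PSF⊗f − g||² + λ||∇f||₁``. Two auxiliary variables are
    split off — v for the image inside the blur (so the data term is solved
    by a direct frequency-domain deblur each iteration) and z for the
    gradient (so the ℓ1 term reduces to soft shrinkage at λ/ρ) — with
    scaled multiplier updates tying both back to f. Iterations stop when
    the relative iterate change drops below ``cfg.tolerance`` or at
    ``cfg.max_iterations`` (reported via the non-converged flag when
    ``full_output=True``). The degraded input is edge-tapered and the
    solves use periodic FFTs; the output is clipped to be nonnegative.
    """
    cfg = cfg or TVRestorationConfig()
    g = np.asarray(degraded, dtype=np.float64)
    if g.ndim != 2:
        raise InputError("degraded image must be 2D")
    if np.any(g < 0):
        raise InputError("degraded image must be nonnegative")
    kernel = _check_psf(psf)
    # replicate-pad so the periodic FFT solves never wrap real content; the
    # pad is stripped from the returned image
    pad = min(2 * (kernel.shape[0] // 2), min(g.shape) // 2)
    if pad:
        g = np.pad(g, pad, mode="edge")
    g = edge_taper(g, kernel)

    shape = g.shape
    H = psf_to_otf(kernel, shape)
    # periodic forward differences; kernel FFT matches grad() below
    dx = np.zeros(shape)
    dx[0, 0], dx[0, -1] = -1.0, 1.0
    dy = np.zeros(shape)
    dy[0, 0], dy[-1, 0] = -1.0, 1.0
    Dx, Dy = np.fft.fft2(dx), np.fft.fft2(dy)

    G = np.fft.fft2(g)
    HtH = np.abs(H) ** 2
    DtD = np.abs(Dx) ** 2 + np.abs(Dy) ** 2
    HtG = np.conj(H) * G

    lam, rho = cfg.lam, cfg.rho

    def grad(a):
        return (np.roll(a, -1, axis=1) - a, np.roll(a, -1, axis=0) - a)

    def objective(a):
        resid = np.real(np.fft.ifft2(np.fft.fft2(a) * H)) - g
        gx, gy = grad(a)
        if cfg.tv_flavor == "anisotropic":
            tv = np.abs(gx).sum() + np.abs(gy).sum()
        else:
            tv = np.hypot(gx, gy).sum()
        return float((resid**2).sum() + lam * tv)

    f = g.copy()
    zx, zy = grad(f)
    b1 = np.zeros(shape)
    bx = np.zeros(shape)
    by = np.zeros(shape)

    history = [objective(f)]
    converged = False
    for _ in range(cfg.max_iterations):
        # v-subproblem: (2 HᵗH + ρ) v = 2 Hᵗg + ρ (f + b1) — direct deblur
        V = (2.0 * HtG + rho * np.fft.fft2(f + b1)) / (2.0 * HtH + rho)
        v = np.real(np.fft.ifft2(V))

        gx, gy = grad(f)
        if cfg.tv_flavor == "anisotropic":
            zx = _shrink(gx + bx, lam / rho)
            zy = _shrink(gy + by, lam / rho)
        else:
            wx, wy = gx + bx, gy + by
            mag = np.hypot(wx, wy)
            scale = np.maximum(mag - lam / rho, 0.0) / np.maximum(mag, 1e-15)
            zx, zy = scale * wx, scale * wy

        # f-subproblem: (I + DᵗD) f = (v − b1) + Dᵗ(z − b)
        rhs = np.fft.fft2(v - b1) + (
            np.conj(Dx) * np.fft.fft2(zx - bx) + np.conj(Dy) * np.fft.fft2(zy - by)
        )
        f_new = np.real(np.fft.ifft2(rhs / (1.0 + DtD)))

        gx, gy = grad(f_new)
        b1 = b1 + f_new - v
        bx = bx + gx - zx
        by = by + gy - zy

        rel = np.linalg.norm(f_new - f) / max(np.linalg.norm(f), 1e-15)
        f = f_new
        history.append(objective(f))
        if rel < cfg.tolerance:
            converged = True
            break

    if pad:
        f = f[pad:-pad, pad:-pad]
    f = np.clip(f, 0.0, None)
    if full_output:
        return TVResult(
            image=f,
            converged=converged,
            n_iterations=len(history) - 1,
            objective_history=np.asarray(history),
        )
    return f


def wiener_deconvolve(
    degraded: np.ndarray,
    psf: GaussianPSFModel | np.ndarray,
    cfg: WienerConfig | None = None,
) -> np.ndarray:
    """Classic Wiener deconvolution F̂ = H*·G / (|H|² + K) in the frequency domain.

    K = 0 reduces to pure inverse filtering (exact on noiseless, periodically
    blurred inputs); large K rejects all frequencies and drives the output
    toward zero. Edge tapering (on by default) suppresses wrap-around
    ringing on non-periodic radiographs.
    """
    cfg = cfg or WienerConfig()
    g = np.asarray(degraded, dtype=np.float64)
    if g.ndim != 2:
        raise InputError("degraded image must be 2D")
    kernel = _check_psf(psf)
    if cfg.edge_taper:
        g = edge_taper(g, kernel)
    H = psf_to_otf(kernel, g.shape)
    G = np.fft.fft2(g)
    denom = np.abs(H) ** 2 + cfg.k
    if cfg.k == 0:
        denom = np.where(denom == 0, 1e-300, denom)
    F = np.conj(H) * G / denom
    return np.real(np.fft.ifft2(F))


def richardson_lucy(
    degraded: np.ndarray,
    psf: GaussianPSFModel | np.ndarray,
    cfg: RLConfig | None = None,
) -> np.ndarray:
    """Richardson–Lucy multiplicative deconvolution.

    Iterates ``f ← f · [(g / (f⊗PSF)) ⊗ PSF′]`` (PSF′ the adjoint/flipped
    kernel) from a flat positive initial guess. Convolutions are periodic
    FFTs, so a normalized PSF conserves total flux exactly from the first
    iteration; nonnegativity is preserved by the multiplicative form.
    """
    cfg = cfg or RLConfig()
    g = np.asarray(degraded, dtype=np.float64)
    if g.ndim != 2:
        raise InputError("degraded image must be 2D")
    if np.any(g < 0):
        raise InputError("degraded image must be nonnegative")
    if g.sum() <= 0:
        raise InputError("degraded image is all zero")
    kernel = _check_psf(psf)
    H = psf_to_otf(kernel, g.shape)
    Hc = np.conj(H)
    f = np.full_like(g, g.mean())
    for _ in range(cfg.n_iterations):
        blurred = np.real(np.fft.ifft2(np.fft.fft2(f) * H))
        ratio = g / np.maximum(blurred, cfg.floor)
        correction = np.real(np.fft.ifft2(np.fft.fft2(ratio) * Hc))
        f = f * correction
    return np.clip(f, 0.0, None)
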