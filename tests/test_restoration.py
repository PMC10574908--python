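"""Deconvolution engines: TV splitting solver, Wiener filter, Richardson–Lucy."""

import numpy as np
import pytest
from skimage.restoration import richardson_lucy as skimage_rl

import adaptpsf as ap
from adaptpsf.psf_mtf import identity_kernel
from conftest import periodic_blur, replicate_blur


PSF2 = ap.gaussian_psf_kernel(2.0)


@pytest.fixture(scope="module")
def degraded_noisy(line_pattern_adu):
    """Thick-detector fixture: sigma 2.61 blur plus its Poisson–Gaussian noise."""
    blurred = replicate_blur(line_pattern_adu, 2.61)
    return ap.synthesize_noise(blurred, ap.NoiseModel(0.29, 7.10), seed=5) / 4095.0


class TestTV:
    def test_identity_kernel_returns_input(self, line_pattern):
        out = ap.deconvolve_tv(
            line_pattern, identity_kernel(), ap.TVRestorationConfig(lam=1e-6)
        )
        assert np.sqrt(((out - line_pattern) ** 2).mean()) < 1e-4

    def test_restoration_oracle_halves_rmse(self, line_pattern):
        blurred = replicate_blur(line_pattern, 2.0)
        rmse_in = np.sqrt(((blurred - line_pattern) ** 2).mean())
        out = ap.deconvolve_tv(blurred, PSF2, ap.TVRestorationConfig(lam=1e-4))
        rmse_out = np.sqrt(((out - line_pattern) ** 2).mean())
        assert rmse_out <= 0.5 * rmse_in

    def test_objective_monotone_descent(self, line_pattern):
        blurred = replicate_blur(line_pattern, 2.0)
        res = ap.deconvolve_tv(
            blurred, PSF2, ap.TVRestorationConfig(lam=1e-4), full_output=True
        )
        obj = res.objective_history
        increases = np.diff(obj) > 1e-9 * np.maximum(np.abs(obj[:-1]), 1.0)
        assert not increases.any()

    def test_matches_reference_minimizer_on_tiny_problem(self):
        # brute-force check: L-BFGS on the Huber-smoothed objective agrees
        from scipy import optimize
        from adaptpsf.restoration import psf_to_otf

        rng = np.random.default_rng(0)
        g = rng.uniform(0, 1, (12, 12))
        lam = 0.05
        kernel = identity_kernel().kernel
        H = psf_to_otf(kernel, g.shape)

        def objective(fv):
            f = fv.reshape(g.shape)
            resid = np.real(np.fft.ifft2(np.fft.fft2(f) * H)) - g
            gx = np.roll(f, -1, axis=1) - f
            gy = np.roll(f, -1, axis=0) - f
            eps = 1e-10
            return (resid**2).sum() + lam * (
                np.sqrt(gx**2 + eps).sum() + np.sqrt(gy**2 + eps).sum()
            )

        ref = optimize.minimize(
            objective, g.ravel(), method="L-BFGS-B",
            options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
        )
        # padding alters the boundary model, so solve the same periodic problem
        res = ap.deconvolve_tv(
            np.pad(g, 6, mode="wrap"),
            identity_kernel(),
            ap.TVRestorationConfig(lam=lam, tolerance=1e-8, max_iterations=2000),
        )[6:-6, 6:-6]
        assert objective(res.ravel()) == pytest.approx(ref.fun, rel=1e-3)

    def test_nonconverged_flag(self, line_pattern):
        blurred = replicate_blur(line_pattern, 2.0)
        res = ap.deconvolve_tv(
            blurred, PSF2,
            ap.TVRestorationConfig(lam=1e-4, tolerance=1e-12, max_iterations=3),
            full_output=True,
        )
        assert not res.converged and res.n_iterations == 3

    def test_unnormalized_psf_rejected(self, line_pattern):
        with pytest.raises(ap.ParameterError):
            ap.deconvolve_tv(line_pattern, PSF2.kernel * 2.0)

    def test_output_nonnegative(self, degraded_noisy):
        out = ap.deconvolve_tv(
            degraded_noisy, ap.gaussian_psf_kernel(2.61), ap.TVRestorationConfig()
        )
        assert out.min() >= 0.0


class TestWiener:
    def test_k0_is_exact_inverse_on_periodic_input(self, line_pattern):
        blurred = periodic_blur(line_pattern, PSF2.kernel)
        rec = ap.wiener_deconvolve(blurred, PSF2, ap.WienerConfig(k=0.0, edge_taper=False))
        assert np.sqrt(((rec - line_pattern) ** 2).mean()) < 1e-6

    def test_large_k_rejects_everything(self, line_pattern):
        out = ap.wiener_deconvolve(line_pattern, PSF2, ap.WienerConfig(k=1e12, edge_taper=False))
        assert np.abs(out).max() < 1e-6

    def test_interior_optimum_under_noise(self, line_pattern_adu):
        degraded = ap.synthesize_noise(
            replicate_blur(line_pattern_adu, 2.0), ap.NoiseModel(0.29, 7.10), seed=2
        )
        ks = [1e-4, 1e-3, 1e-2, 1e-1, 1.0]
        rmses = []
        for k in ks:
            rec = ap.wiener_deconvolve(degraded, PSF2, ap.WienerConfig(k=k))
            rmses.append(np.sqrt(((rec - line_pattern_adu) ** 2).mean()))
        best = int(np.argmin(rmses))
        assert 0 < best < len(ks) - 1

    def test_negative_k_rejected(self):
        with pytest.raises(ap.ParameterError):
            ap.WienerConfig(k=-0.1)


class TestRichardsonLucy:
    def test_flat_image_is_fixed_point(self):
        flat = np.full((32, 32), 5.0)
        out = ap.richardson_lucy(flat, PSF2, ap.RLConfig(n_iterations=9))
        np.testing.assert_allclose(out, flat, rtol=1e-10)

    def test_nonnegativity_and_flux_conservation(self, line_pattern):
        blurred = periodic_blur(line_pattern, PSF2.kernel).clip(0, None)
        out = ap.richardson_lucy(blurred, PSF2, ap.RLConfig(n_iterations=15))
        assert out.min() >= 0.0
        assert out.sum() == pytest.approx(blurred.sum(), rel=1e-3)

    def test_point_source_sharpens(self):
        point = np.zeros((64, 64))
        point[32, 32] = 100.0
        blurred = periodic_blur(point, PSF2.kernel).clip(0, None)
        ratios = [
            (lambda f: f.max() / f.sum())(
                ap.richardson_lucy(blurred, PSF2, ap.RLConfig(n_iterations=n))
            )
            for n in range(1, 11)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_agrees_with_independent_implementation(self, line_pattern):
        # same multiplicative iteration, independent code path (zero-padded
        # boundaries there, so compare away from the borders)
        blurred = replicate_blur(line_pattern, 2.0)
        mine = ap.richardson_lucy(blurred, PSF2, ap.RLConfig(n_iterations=10))
        theirs = skimage_rl(blurred, PSF2.kernel, num_iter=10, clip=False)
        inner = (slice(20, -20), slice(20, -20))
        assert np.abs(mine[inner] - theirs[inner]).max() < 0.02

    def test_all_zero_input_rejected(self):
        with pytest.raises(ap.InputError):
            ap.richardson_lucy(np.zeros((16, 16)), PSF2)


class TestNoiseAmplificationOrdering:
    def test_tv_sharpens_with_less_noise_than_wiener(self, degraded_noisy, line_pattern):
        """TV at lambda=0.01 raises GM over the input while keeping flat-region
        noise below small-K Wiener output — the regularization tradeoff."""
        psf = ap.gaussian_psf_kernel(2.61)
        tv = ap.deconvolve_tv(degraded_noisy, psf, ap.TVRestorationConfig(lam=0.01))
        wiener = np.clip(
            ap.wiener_deconvolve(degraded_noisy, psf, ap.WienerConfig(k=1e-4)), 0, None
        )
        _, gm_in = ap.gradient_magnitude(degraded_noisy)
        _, gm_tv = ap.gradient_magnitude(tv)
        assert gm_tv > gm_in
        flat = (slice(148, 158), slice(2, 30))  # inside a wide bright bar
        assert tv[flat].std() < wiener[flat].std()
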