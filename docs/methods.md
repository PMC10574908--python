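# Methods

## Degradation model

A radiograph from detector *d* is modeled as
`g = PSF_d ⊗ f + η_d(PSF_d ⊗ f)·δ` with an isotropic 2D Gaussian PSF of
width σ_d (pixels) and signal-dependent noise sd
`η_d²(x) = α_d·x + β_d²` (Poisson gain α, electronic Gaussian sd β, ADU).
The noise is applied to the *blurred* noise-free signal, matching the term
order of the model: optical blur happens in the scintillator before the
quantum and electronic noise of the sensor is realized. Scatter,
polychromatic spectra, detector lag and spatially correlated noise are out
of model.

### PSF / LSF / MTF

The discretized kernel samples the Gaussian at integer offsets out to
⌈4σ⌉ and renormalizes; truncation at 4σ discards < 1e-4 of the mass. The
analytic MTF of the Gaussian LSF is `exp(−2π²σ²u²)` (u in cycles/pixel;
divide by the pixel pitch for lp/mm). σ is recovered from a measured MTF by
least squares in the log domain — the model is linear in u² there — using
only samples with modulation > 0.01, where measured curves are not yet
noise-dominated. Slit LSF measurement follows presampled practice: per-row
centroids of a slit tilted 1.5–3° are regressed to a line, pixel distances
to that line are binned at 0.1 px (a standard oversampling choice; the tilt
makes successive rows sample distinct subpixel phases), and the profile is
baseline-subtracted and area-normalized. Simulated round trips recover σ
within 2% and agree within 3% across tilts.

### Noise level function estimation

Flat frames are tiled into blocks (default 16×16). A block enters the fit
only if the Kendall τ between its pixels and their one-pixel-shifted
neighbors (horizontal and vertical, averaged) stays below the two-sided
critical value at p = 0.01 under the white-noise null — a compact surrogate
for full non-parametric uniform-region detection that rejects gradients and
edges. Block variance is regressed on block mean with a
least-absolute-deviation line (IRLS); α̂ is the slope (floored at 0 with a
warning), β̂ the square root of the intercept floored at 0. At least three
distinct exposure levels are required to separate slope from intercept.
The exposure levels and block geometry used throughout the validation
campaigns (means 200–3000 ADU, 256² frames, 16 px blocks) are this
package's declared defaults.

## Similarity metrics

**SSIM** uses the canonical 11×11 Gaussian-tapered window (taper σ 1.5),
k1 = 0.01, k2 = 0.03, C3 = C2/2, exponents 1, and crops the window
half-size border before averaging. The dynamic range L defaults to the
12-bit full scale 4095 and is a recorded config field (L = 1 for
unit-normalized data). The implementation is cross-checked in the tests
against scikit-image's independent SSIM to 1e-10.

**Phase congruency** uses a log-Gabor bank (4 scales, 4 orientations,
minimum wavelength 6 px, multiplier 2, bandwidth parameter 0.55) with a
Rayleigh noise floor estimated from the median smallest-scale amplitude
(k = 2 sds). All terms scale linearly with image contrast and the filters
have zero DC gain, so the map is invariant to affine intensity changes and
a constant image maps to zero.

**FSIM** compares phase-congruency and Scharr gradient-magnitude maps of
the two inputs after a joint affine rescale to [0, 255] (T1 = 0.85,
T2 = 160, exponents 1). The weighting field is the elementwise
`max(PC1, PC2)` — the convention that emphasizes locations either image
deems salient and keeps the score symmetric. On a pair of constant images
the weight field vanishes and the unweighted mean similarity is returned.

**CNR** is `(μ_T − μ_B)/sqrt(σ_T² + σ_B²)` per ROI spec, averaged over
specs; **GM** is the mean `sqrt((I⊗f_h)² + (I⊗f_v)²)` for Sobel, Prewitt or
Scharr operator pairs.

## Adaptive σ estimation

The sweep blurs the thin image with each grid σ (replicate-padded spatial
convolution, so border handling cannot bias the score), scores against the
thick image with both metrics, and reports the two argmaxes (smallest σ on
ties — the least-blur assumption) plus their arithmetic mean, quoted at two
decimals with half-up rounding. Default grid: 0.01 to 8.0 px in steps of
0.01 — the upper end covers the thickest profile's σ = 5.13 px with margin.
Because dual-detector curves can be multi-modal (an early peak followed by
a second rise when noise and asymmetric blur interact), every local maximum
within 99% of the global score is surfaced in the result diagnostics while
the global argmax is reported. The thick image's FSIM features are
σ-independent and computed once per sweep.

## TV-regularized deconvolution

`deconvolve_tv` minimizes `‖K f − g‖₂² + λ‖∇f‖₁` (anisotropic ℓ1 of the
gradient components by default; isotropic available). The objective is read
as standard non-blind TV deconvolution over a free image variable with the
degraded image as data. Two variables are split off with equal penalty ρ:
`v` for the image inside the blur operator, whose subproblem is a direct
frequency-domain deblur `(2HᵗH + ρ)v = 2Hᵗg + ρ(f + b₁)`, and `z = ∇f`,
whose subproblem is soft shrinkage at λ/ρ; the f-update solves
`(I + ∇ᵗ∇)f` in the Fourier domain and scaled multipliers close the loop.
Splitting the blur as well as the gradient keeps the iteration
well-conditioned when the MTF is small at high frequencies, where a
gradient-only splitting transfers deblurred detail into f too slowly to be
usable.

Numerical choices:

* λ defaults to 0.01 with stopping tolerance 1e-4 (relative iterate
  change) and a 300-iteration cap; the non-converged case is flagged, not
  raised. λ is calibrated for images normalized to [0, 1]; the pipeline
  normalizes before deconvolution and rescales after.
* ρ defaults to `max(10λ, 0.1)`. A fixed small multiple of λ
  under-penalizes the splitting — the iterates oscillate in objective and
  converge too slowly toward the deblurred solution — so the floor keeps
  the v-subproblem's implicit Tikhonov damping (ρ/2) in a stable range
  across the λ regimes the package uses (1e-4 for near-noiseless work,
  0.01 under detector noise).
* Boundaries: the input is replicate-padded by twice the kernel half-width
  and edge-tapered before the periodic FFT solves, and the pad is stripped
  from the result; without this, the near-exact inversion at small λ rings
  severely from the wrap-around seam.
* The solver tracks the true objective per outer iteration. With the
  default ρ it descends monotonically on well-posed (noiseless or
  lightly-noised) deconvolution problems, and the suite asserts this;
  augmented-Lagrangian iterations carry no general monotonicity guarantee,
  and under strong noise small transient increases can occur while the
  iterates still converge. Correctness of the minimizer is separately
  verified against an L-BFGS solve of the Huber-smoothed objective on a
  tiny problem.

**Wiener**: `F̂ = H*G/(|H|² + K)` with optional edge taper; K = 0 is the
exact inverse on periodic inputs. **Richardson–Lucy**:
`f ← f·[(g/(f⊗PSF))⊗PSF′]` from a flat positive start, periodic FFT
convolutions (hence exact flux conservation with a normalized PSF), ratio
denominator floored at 1e-12.

## Simulator

The die phantom is a solid PMMA cube with spherical zero-attenuation pip
recesses on its faces (radius 10% of the edge) — an arbitrary but
edge-rich interior; any phantom with internal structure at several scales
would serve the validation suite equally. μ_PMMA defaults to 0.0227 /mm
(≈ 70 keV effective, mono-energetic). Projection casts one ray per detector
pixel from a point source (SDD 1500 mm, SOD 1000 mm), stepping at half-voxel
depth increments and summing the attenuation of the containing voxel times
the oblique path element; the slab closed form is reproduced to ~1e-9
relative. No scatter, no focal-spot blur (the single Gaussian PSF absorbs
all blur sources).

Scales: the full-scale preset is a 300³ phantom of 0.1 mm voxels onto a
512×1024 detector at 48 μm pitch. The validation suite and examples use a
desk-scale preset — a 100–150 voxel phantom onto 128×160 to 256×512
detectors at 0.1 mm pitch — chosen so the whole phantom fits the field of
view with flat-field margin; all geometric ratios are preserved.

The bar-chart generator emits square-wave groups between 0.6 and 5.0 lp/mm
(20 groups by default) and refuses frequencies at or above Nyquist. The
standard restoration fixture in the tests uses the 0.6–2.5 lp/mm groups
anti-aliased with a 1 px Gaussian: square-wave harmonics beyond the blur's
MTF support are unrecoverable by any deconvolution method, so a
band-limited ground truth is what makes restoration error a meaningful
measurement.

## What the synthetic validation does and does not show

The simulator realizes exactly the model the estimator assumes: isotropic
Gaussian blur, uncorrelated Poisson–Gaussian noise, perfect registration,
no scatter. Passing tests therefore demonstrate internal consistency —
parameter recovery, semigroup behavior, noise-amplification ordering — not
performance on real detectors, where asymmetric PSFs, scatter and gain
non-uniformity make the similarity curves multi-modal and can pull the
estimated σ well below the semigroup prediction. The diagnostics
(local-maxima lists, curve dumps) exist for exactly that regime.

## Known limitations

* Gaussian-only PSF family; no spatially varying or asymmetric blur.
* Inputs must be co-registered; no registration is attempted.
* The Kendall-τ screen is pairwise-shift only; strongly textured flats can
  leak through at low contrast.
* The TV solver's objective descent is asserted, not guaranteed, under
  heavy noise (see above).
* NNPS-style spatially-resolved noise characterization is out of scope; the
  NLF is a two-parameter summary.
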