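# adaptpsf

Adaptive point-spread-function estimation and noise-controlled restoration
for dual-scintillator X-ray radiography.

## The problem

Indirect-conversion flat-panel detectors convert X-rays to light in a
scintillator layer. A thick layer absorbs more photons — less noise — but
spreads the light laterally, blurring the image; a thin layer is sharp but
noisy. `adaptpsf` is for detector physicists and imaging researchers who have
(or can simulate) *two* co-registered radiographs of the same scene, one from
a thin and one from a thick scintillator, and want the thick image restored
to the thin image's resolution without paying the full noise-amplification
price of classical deconvolution.

## The method

The system is modeled as a linear shift-invariant degradation

```
g = PSF ⊗ f + η(f)·δ,      η²(x) = α·x + β²
```

with an isotropic Gaussian PSF of width σ (pixels) and Poisson–Gaussian
pixel noise (Poisson gain α, electronic sd β ADU). Three stages:

1. **Adaptive σ estimation.** For each candidate σ on a grid, the thin image
   is blurred with the Gaussian PSF of that width and compared to the thick
   image with two full-reference metrics: SSIM (windowed luminance /
   contrast / structure) and FSIM (phase-congruency- and gradient-weighted
   feature similarity). The final width is the average of the two argmaxes:
   `σ_final = (σ_SSIM + σ_FSIM) / 2`. On noiseless Gaussian pairs this
   recovers the semigroup value `sqrt(σ_thick² − σ_thin²)`.
2. **Non-blind TV deconvolution.** The thick image is restored by minimizing
   `‖PSF_σ ⊗ f − g‖₂² + λ‖∇f‖₁` (λ = 0.01 on unit-normalized images) with an
   augmented-Lagrangian variable-splitting solver: frequency-domain quadratic
   solves, soft shrinkage on the split gradient, multiplier updates,
   stopping at relative change 1e-4. Wiener filtering and Richardson–Lucy
   are included as reference engines.
3. **Validation without hardware.** A simulator provides a voxelized PMMA
   die phantom, cone-beam Beer–Lambert projection (SDD 150 cm, SOD 100 cm),
   per-detector Gaussian blur and Poisson–Gaussian noise; an NLF estimator
   recovers (α, β) from flat-field frames via block mean–variance regression
   with a Kendall-τ uniformity screen; slit-image LSF measurement and
   MTF fitting recover σ the way it is measured on real detectors.

Three packaged detector profiles (Gd₂O₂S:Tb scintillators of 84/96/140 μm on
48 μm pixels, 12-bit ADC) carry the measured operating points:
σ = 1.79/2.61/5.13 px, α = 0.37/0.29/0.08, β = 9.12/7.10/3.31 ADU.

## Worked example

`examples/03_sigma_sweep.py` blurs a bar-pattern scene with σ = 1.0 (thin
stand-in) and σ = 2.0 (thick stand-in) and sweeps candidates:

```
SSIM-optimal sigma: 1.75 px
FSIM-optimal sigma: 1.75 px
final (averaged)  : 1.75 px
semigroup target  : 1.73 px (the width that maps the sharp image onto the blurry one)
```

Both metrics peak within one grid step (0.05 px) of the analytic value.
`examples/04_restoration.py` then degrades the same scene with the medium
profile's blur and noise and compares engines:

```
image          rmse  mean GM  flat sd
degraded     0.1112   0.2432   0.0431
tv           0.0737   0.4004   0.0726
wiener       0.2938   1.3671   0.4183
rl           0.0736   0.5076   0.1160
```

TV restoration sharpens (mean gradient magnitude 0.24 → 0.40) and lowers the
RMSE to the clean scene, while the lightly regularized Wiener inverse
amplifies flat-field noise tenfold (sd 0.04 → 0.42) — the tradeoff the
adaptive-σ + TV combination is designed to control. The other examples cover
PSF/MTF round trips, noise-parameter recovery, and the end-to-end pipeline
on simulated dual-detector projections.

A thin CLI wraps the same functions:

```bash
adaptpsf simulate --profile detector1 --profile detector2 --seed 7 --out pair/
adaptpsf run --thin pair/detector1.tif --thick pair/detector2.tif --out result/
adaptpsf deconvolve --in g.tif --sigma 1.09 --method tv --out f.tif
```

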