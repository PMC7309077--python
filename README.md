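# mrftv

Compressed-sensing MRI reconstruction with a composite **Markov-random-field
+ total-variation** prior.

Accelerated MRI acquisitions keep only a fraction of the k-space (spatial
frequency) samples, and the missing information must be supplied by a prior on
the image. `mrftv` implements an iterative reconstruction that couples two
complementary priors: an anisotropic Ising/MRF model on the *support* of the
non-decimated wavelet coefficients — capturing the spatial clustering of
significant coefficients, with all of its parameters estimated from the data
on the fly — and isotropic total variation on the image. It is aimed at
researchers studying sparsity-promoting MRI reconstruction who want a
self-contained, fully synthetic-testable implementation with single-coil,
complex-image and multi-coil (SENSE-style) acquisition models.

## The model

Measurements are `y = A x + n` with `A` the partially observed orthonormal
2-D DFT and `n` i.i.d. complex Gaussian noise (multi-coil: `y_i = A C_i x`
with known sensitivity maps `C_i`). The estimate solves

```
min_x  ½‖y − Ax‖₂² + ψ_MRF(Wx) + τ₂‖x‖_TV
```

where `W` is a Parseval-normalized stationary (undecimated) wavelet frame and
`ψ_MRF` is the negative log of a joint model for coefficients `θ = Wx` and a
hidden label field `s ∈ {−1,+1}`: significant coefficients (`s_i = +1`) follow
a Laplacian truncated to `|θ_i| ≥ B`, insignificant ones to `|θ_i| < B`, and
`s` has a Gibbs prior with energy

```
H(s) = Σ_i α s_i − Σ_<i,j> β_o s_i s_j ,   o ∈ {h, v, d1, d2},
```

whose orientation-specific interactions `β_o` make the clustering
anisotropic. Per outer iteration the solver

1. takes a gradient step on the data term, `x_g = r − μ A^H(A r − y)`;
2. MAP-estimates the support `ŝ` of `Wx_g` by warm-started Metropolis
   sampling, with `(α, β_o)` re-estimated from lag-1 correlations of the
   squared significant coefficient magnitudes and `B, b` from robust subband
   statistics;
3. applies a closed-form, support-conditioned **soft-thresholding** proximal
   rule to the coefficients (for `ŝ = +1` the output magnitude is kept at or
   above `B`; for `ŝ = −1` it is shrunk and capped at `B`);
4. applies the TV proximal map (Chambolle dual projection) to `x_g`;
5. averages the two proximal outputs and (optionally) adds Nesterov momentum
   `r ← x_k + (t_k−1)/t_{k+1} (x_k − x_{k−1})`.

With momentum the solver is called **FCLaTV**; without it, **CLaTV**. The
defaults `μ = τ₁ = τ₂ = 1` are used throughout. See `docs/methods.md` for the
full description, parameter table and design rationale.

## Worked example

```python
import numpy as np
import mrftv

truth = np.abs(mrftv.make_phantom(mrftv.PhantomSpec(
    shape=(128, 128), kind="piecewise_texture", seed=0)))
mask = mrftv.radial_mask_for_rate((128, 128), rate=0.25, seed=0)
data = mrftv.simulate_measurements(truth, mask, sigma=0.5, seed=0)

zero_filled = np.abs(data.adjoint(data.y))
print(f"zero-filled PSNR: {mrftv.psnr(zero_filled, truth):.2f} dB")

model = mrftv.CompositeMRFTVModel(data, max_iters=100)
result = model.fit(reference=truth, seed=1)
print(result.summary())
```

Output:

```
zero-filled PSNR: 24.01 dB
Composite MRF + TV reconstruction
================================================
algorithm:        FCLaTV (magnitude mode)
image shape:      (128, 128)
coils:            1
sampling rate:    0.2446 (radial)
wavelet:          db4, 3 stationary scales
mu/tau1/tau2:     1.0/1.0/1.0
iterations:       100 (converged: False)
final data resid: 8.3343e+01
final PSNR:       35.29 dB
final SSIM:       0.9329
final RLNE:       0.0337
finest-subband MRF parameters (HH1):
  alpha = 0.0051, beta(h,v,d1,d2) = (0.646, 0.475, 0.297, 0.519)
```

Reading the numbers: the phantom is a piecewise-smooth textured magnitude
image in [0, 255]; keeping ~24.5% of k-space along radial lines and
zero-filling the rest gives 24.0 dB PSNR, while the composite-prior
reconstruction reaches 35.3 dB (RLNE 0.034, i.e. 3.4% relative error). The
estimated `β` vector has unit ℓ2 norm; the small `α` says significant
coefficients are not heavily penalized a priori, and `β_h` being largest says
the finest diagonal subband clusters most strongly in the horizontal
direction for this phantom. `result.history` is a per-iteration DataFrame
(PSNR/SSIM/RLNE, data residual, MRF parameter track).

The same pipeline is available from the shell:

```sh
mrftv simulate --kind piecewise_texture --shape 128 128 --mask radial \
      --rate 0.25 --seed 0 --out meas.npz --ref ref.nii
mrftv reconstruct --input meas.npz --algo fclatv --iters 100 --seed 1 \
      --ref ref.nii --out recon.nii --log history.csv
mrftv metrics --ref ref.nii --test recon.nii --max-mr 255
```

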