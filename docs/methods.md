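# Methods

## Problem and model

We reconstruct a complex image `x ∈ C^N` from undersampled Fourier
measurements `y = A x + n`, where `A` is the orthonormal 2-D DFT restricted
to a boolean sampling mask and `n` is i.i.d. circular complex Gaussian noise.
For multi-coil data the operator becomes `M = [A C_1; …; A C_Nc]` with known
complex sensitivity maps `C_i`; its adjoint is `M^H y = Σ_i conj(C_i) ⊙ A^H
y_i`. We never materialize these operators: they are implemented as
forward/adjoint function pairs, which is mathematically identical and
memory-sane.

The prior has two parts.

**Wavelet-domain MRF prior.** Let `θ = W x` be the stationary (undecimated)
wavelet frame of the image, 3 scales of `db4` by default, normalized so `W`
is a Parseval tight frame (`W^H W = I`, energy preserved; verified to
~1e−14). Each detail subband carries a hidden binary significance field `s`:
conditioned on `s_i = +1`, `θ_i` follows a Laplacian truncated to
`|θ_i| ≥ B`; conditioned on `s_i = −1`, the same Laplacian truncated to
`|θ_i| < B`. The field `s` has a Gibbs prior `P(s) ∝ exp(−H(s)/T)` with

    H(s) = Σ_i α s_i − Σ_<i,j> β_o s_i s_j,

pair cliques being the 8-neighborhood split into orientations h, v, d1
(main diagonal), d2 (anti-diagonal), each pair counted once, no wraparound.
The interaction enters with a minus sign so that *positive* `β_o` rewards
equal neighbor labels: a ferromagnetic convention, chosen so that the
correlation-based estimates below (which are nonnegative by construction)
encourage clustering rather than penalize it.

**Total variation.** Isotropic TV, `Σ sqrt(|Δ_v x|² + |Δ_h x|²)` with
forward differences truncated at the boundary.

## Solver

Per outer iteration `k` (FCLaTV):

1. `x_g = r − μ M^H(M r − y)` — gradient step; with the orthonormal DFT
   scaling this step is non-expansive for `μ ≤ 1` (and for sum-of-squares-1
   coil maps in the multi-coil case).
2. `θ_g = W x_g`; estimate `B`, per-subband `b`, per-subband `(α, β_o)`;
   MAP-estimate the support `ŝ` by Metropolis sweeps warm-started from the
   previous iteration's support.
3. `x₁ = W^H prox(θ_g | ŝ)` using the closed-form support-conditioned
   soft-thresholding rule below; the approximation coefficients pass through
   unthresholded.
4. `x₂ = prox of μτ₂·TV at x_g` (Chambolle dual projection).
5. `x_k = (x₁ + x₂)/2`.
6. `t_{k+1} = (1 + sqrt(1 + 4 t_k²))/2`,
   `r = x_k + ((t_k − 1)/t_{k+1})(x_k − x_{k−1})`.

CLaTV omits step 6 and sets `r = x_k`. Initialization is the zero-filled
adjoint `x₀ = M^H y` (the standard baseline; the momentum scalar starts at
`t₁ = 1`). Stopping: `max_iters` (default 100) or relative iterate change
below `tolerance` (default 1e−5). The two prox maps are evaluated in
parallel on the same `x_g` and averaged because a joint proximal map of the
two regularizers has no tractable form.

**Modes.** `magnitude` keeps a real iterate (the real part of the gradient
step) — appropriate when the ground truth is a magnitude image.
`complex` and `multicoil` keep a complex iterate and apply steps 2–4
separately to the real and imaginary parts, each with its own support
fields and parameters; the two regularized parts are recombined into the
complex iterate. Sharing a single support between the parts was the main
alternative; independent fields are simpler and performed equally well on
the synthetic suite.

## The soft-thresholding rule

For one coefficient with proximal argument `θ_g`, threshold `B`, shrinkage
`t = μτ₁/b` (see "the b parameter" below):

    ŝ = +1:  B·sgn(θ_g)        if |θ_g| ≤ t + B
             θ_g − t·sgn(θ_g)  otherwise
    ŝ = −1:  0                 if |θ_g| ≤ t
             θ_g − t·sgn(θ_g)  if t < |θ_g| ≤ t + B
             B·sgn(θ_g)        if |θ_g| > t + B

This is the exact minimizer of the truncated-Laplacian penalty plus the
scaled quadratic, verified against a brute-force 1-D grid oracle on random
tuples. It is odd, continuous in `θ_g` for each fixed label, and degenerates
to classical soft-thresholding for `ŝ = +1` when `B = 0` (for `ŝ = −1`,
`B = 0` leaves only the origin as feasible, so the output is 0). For complex
coefficients the rule acts on the magnitude and preserves the phase. Because
the rule moves coefficients continuously instead of hard-selecting them, the
PSNR trajectory is monotone after burn-in on noiseless phantoms (asserted in
the test suite for CLaTV: no per-iteration drop above 0.1 dB after
iteration 10).

## Parameter estimation

All estimated once per outer iteration per subband (per channel in complex
mode):

* **Threshold `B`** (coefficient units): `B = k_σ · σ̂`,
  `σ̂ = median(|HH1|)/0.6745`, the standard MAD noise estimate from the
  finest diagonal subband; `k_σ = 3` by default (a conventional
  3-sigma significance cut). Applied globally to all detail subbands.
* **Laplacian scale `b`** (coefficient units): mean excess
  `mean(|θ_i| − B : |θ_i| ≥ B)`, the ML estimator of a Laplacian scale from
  its tail; falls back to `mean|θ_i|` when no coefficient exceeds `B`, and
  is floored at 1e−8.
* **Interactions `β_o`**: with `θ_S` the subband restricted to coefficients
  currently labeled significant (others zeroed), compute the lag-1
  correlation sums of squared magnitudes
  `r(i,j) = Σ |θ_S(k,l)|²·|θ_S(k+i,l+j)|²` for the four smallest shifts
  (horizontal, vertical, two diagonals; in-bounds pairs only), and normalize
  the 4-vector to unit ℓ2 norm. Squaring both factors suppresses the
  influence of small noisy coefficients. The normalization is a convention
  (only relative sizes matter in the prior) that keeps every `β_o` in
  [0, 1]; boundary truncation makes the constant-field values approach 0.5
  with an O(1/n) lattice-edge correction.
* **Bias `α`**: mean coefficient energy of `θ_S` relative to its largest
  coefficient energy, `α = ‖θ_S‖₂²/(N·‖θ_S‖_max²) ∈ [1/N, 1]`. Sparse
  subbands get small `α` (little a-priori pressure toward `−1`).
  Degenerate cases: all-zero `θ_S` returns `β = (½,½,½,½)`, `α = 0`; no
  co-occurring significant pairs keeps the uniform `β`.

**MAP support.** The posterior energy is `Σ_i D_i(s_i) + H(s)` where the
data term is the Laplacian penalty `|θ_i|/b` when the label agrees with the
truncation region and a finite penalty `γ` when it disagrees. Replacing the
truncation's infinity by `γ` (default `10·max_i |θ_i|/b`, floored at 1)
keeps Metropolis flips possible while recovering the exact MAP limit as
`γ → ∞`. Sampling is raster-scan single-site Metropolis at fixed `T = 1`,
3 sweeps per outer iteration (warm starts across iterations make this
sufficient), with the best-visited configuration returned; uniforms are
pre-drawn from a seeded generator, so runs are bit-reproducible, and the
numba-compiled kernel and the pure-Python fallback consume randomness
identically. On 3×3 and 4×4 lattices 500 sweeps recover the exhaustive
global minimum on 100/100 random instances in the test suite.

## The `b` parameter

The truncated-Laplacian density can be parameterized by a scale `s`
(`p ∝ e^{−|θ|/s}`) or its reciprocal rate. `estimate_scale` returns the
scale (mean excess). The shrinkage amount in the thresholding rule is the
penalty weight times `μτ₁`, i.e. `μτ₁/scale`: subbands with heavy-tailed,
signal-rich statistics (large scale) get *small* shrinkage, noise-dominated
subbands get larger shrinkage, and the `ŝ = −1` branch caps whatever
survives at `B`. The opposite composition (shrinking by `μτ₁·scale`) was
evaluated and rejected: it biases significant coefficients by their own mean
excess, costing ~9 dB on the 25% radial benchmark and breaking the
clean-data consistency of the solver.

## Synthetic data

The generators emulate the input classes the method consumes:

* `shepp_logan`: the classic ellipse phantom (anti-aliased resize to the
  requested grid), scaled to [0, 255].
* `piecewise_texture`: piecewise-constant regions from thresholded smoothed
  Gaussian noise inside a circular support, plus band-limited
  (difference-of-Gaussians) texture of amplitude 20 by default — exercising
  both the TV assumption (flat regions) and the wavelet-clustering
  assumption (texture, edges).
* `complex_phase`: the textured magnitude times `exp(iφ)` with a smooth
  random low-order polynomial phase, emulating field-inhomogeneity phase.
* Coil maps: Gaussian profiles centered per-quadrant with gentle linear
  phase, normalized to unit pointwise sum of squares (so `M^H M = I` at full
  sampling).
* Noise: i.i.d. circular complex Gaussian per k-space sample.

What the generators do **not** emulate: real anatomy and its contrast
mechanisms, structured/correlated scanner noise, non-Cartesian acquisition
geometry, sensitivity-map estimation error, motion or B0 artifacts. Passing
tests therefore establish the correctness and relative behavior of the
algorithmic machinery on piecewise-smooth textured images, not clinical
image quality.

## Numerical choices

* DFT: orthonormal scaling both directions, DC-centered masks,
  `ifftshift`/`fftshift` handled inside the operators, raster order over
  mask positions.
* Wavelets: `pywt.swt2/iswt2` with unit-energy normalization; periodic
  boundary (the stationary transform's native extension); image dimensions
  must be multiples of `2^scales`.
* Ties: `|θ| = B` is labeled significant.
* TV prox: Chambolle dual projection, step 0.248, 20 inner iterations by
  default; complex images are processed per real/imaginary part. The primal
  objective of the early dual iterates can transiently exceed the input's
  (the dual, not the primal, is monotone); it converges to the same optimum
  as an independent implementation to 1e−2 relative.
* Sampling masks: radial lines rasterized by nearest-neighbor stepping at
  equispaced angles starting at 0; random masks use exact-count sampling
  without replacement, variable density ∝ `(1 + r/r₀)^−2` with `r₀` an
  eighth of the grid half-width; DC always included; golden-ratio line
  selection advances 111.246° from the previously *selected* line and snaps
  to the nearest free angle.
* Metrics: PSNR/SSIM/RLNE on magnitudes; SSIM uses a Gaussian window with
  σ = 1.5 (11×11 support), `C1 = (0.01·MAX)²`, `C2 = (0.03·MAX)²`;
  identical images report infinite PSNR.

## Known limitations

* The objective is non-convex (the MRF support term); the solver is a
  heuristic block-coordinate/proximal scheme with no convergence guarantee.
  Empirically it converges on the whole synthetic suite.
* At full sampling with no noise the reconstruction does not return the
  ground truth exactly: the fixed point averages the TV-prox and MRF-prox
  outputs of the clean image, and with `τ₂ = μ = 1` on a [0, 255] image the
  TV prox carries an irreducible edge bias of roughly 1% RLNE, leaving a
  consistency floor of ~0.5–0.6% (measured: 0.63% on the 64×64 ellipse
  phantom by `scripts/acceptance.py`). Scaling `τ₂` down with the expected
  noise level would remove this floor but departs from the fixed
  `τ₂ = 1` convention used everywhere else.
* The Metropolis MAP step is exact only in the exhaustively checkable
  small-lattice regime; on full subbands it is a few-sweep approximation.
* Non-Cartesian (NUFFT/gridding) acquisition is out of scope; the
  golden-ratio selector operates on line *angles* only.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use 64×64 phantoms for
consistency, acceleration (5 seeds × 100 iterations × both solvers) and
complex/multi-coil checks, and a 128×128 phantom at 25% radial sampling for
the main undersampling benchmark; oracle comparisons run on 1,000 random
prox tuples and 100 random 3×3/4×4 MAP instances. These sizes were chosen so
the full verification runs in about a minute while every check remains
discriminative (the 128×128 benchmark reproduces the same ~11 dB gain
observed at 64×64).
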