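"""Anisotropic Markov-random-field significance model for wavelet subbands.

Each detail subband carries a binary field ``s`` on the coefficient lattice:
``s_i = +1`` where the coefficient is significant (``|theta_i| >= B``) and
``-1`` otherwise.  The Gibbs prior ``P(s) = Z^{-1} exp(-H(s)/T)`` uses the
pair-clique energy

    H(s) = sum_i alpha * s_i  -  sum_{<i,j>} beta_o * s_i * s_j

with orientation-specific interaction strengths ``beta_o`` for horizontal,
vertical and the two diagonal neighbor pairs of the 8-neighborhood.  The
interaction enters with a negative sign so that positive ``beta_o`` rewards
equal neighbor labels (ferromagnetic clustering).

The conditional coefficient model is a truncated Laplacian: significant
coefficients live on ``|theta| >= B``, insignificant ones on ``|theta| < B``.
For MAP support estimation the truncation's infinite penalty is replaced by a
finite disagreement penalty ``gamma`` so that Metropolis label flips remain
possible; the MAP limit is recovered as ``gamma -> inf``.

Parameters are data-driven: ``B`` from a robust noise estimate of the finest
diagonal subband, ``b`` as the per-subband mean excess over ``B``, and
``(alpha, beta_o)`` from lag-1 correlations of squared significant-coefficient
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _metropolis
from .operators import WaveletCoefficients

__all__ = [
    "SupportField",
    "MRFParams",
    "LaplacianParams",
    "estimate_threshold",
    "estimate_scale",
    "threshold_labels",
    "init_support",
    "mrf_energy",
    "posterior_energy",
    "map_support",
    "estimate_mrf_params",
]

#: MAD-to-sigma conversion for a Gaussian distribution.
_MAD_SCALE = 0.6745

#: lower clamp for the Laplacian scale estimate
SCALE_FLOOR = 1e-8


@dataclass
class SupportField:
    """Binary significance labels on one subband lattice, entries in {-1,+1}."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.size and not np.all(np.abs(labels) == 1):
            raise ValueError("labels must be -1 or +1")
        self.labels = labels

    @property
    def shape(self):
        return self.labels.shape

    def copy(self) -> "SupportField":
        return SupportField(self.labels.copy())


@dataclass
class MRFParams:
    """Gibbs-prior parameters: site bias, orientation interactions, temperature."""

    alpha: float = 0.0
    beta_h: float = 0.5
    beta_v: float = 0.5
    beta_d1: float = 0.5
    beta_d2: float = 0.5
    temperature: float = 1.0

    @property
    def betas(self):
        return (self.beta_h, self.beta_v, self.beta_d1, self.beta_d2)


@dataclass
class LaplacianParams:
    """Truncated-Laplacian conditional parameters for one subband.

    ``scale_b`` is the Laplacian scale (the mean excess over the threshold);
    the corresponding penalty in the negative log-likelihood is
    ``|theta| / scale_b``, i.e. the rate ``1/scale_b`` multiplies the
    magnitude.  The soft-thresholding shrinkage amount is ``mu / scale_b``.
    """

    threshold_B: float
    scale_b: float

    @property
    def rate(self) -> float:
        return 1.0 / self.scale_b

    def __post_init__(self):
        if self.threshold_B < 0:
            raise ValueError("threshold_B must be >= 0")
        if self.scale_b <= 0:
            raise ValueError("scale_b must be > 0")


# --------------------------------------------------------------------------
# parameter estimation


def estimate_threshold(theta: WaveletCoefficients, k_sigma: float = 3.0) -> float:
    """Significance threshold ``B = k_sigma * sigma_hat`` with the robust
    noise estimate ``sigma_hat = median(|HH1|) / 0.6745`` from the finest
    diagonal subband."""
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    hh1 = np.asarray(theta.finest_diagonal)
    if hh1.size == 0:
        raise ValueError("finest diagonal subband is empty")
    sigma = float(np.median(np.abs(hh1))) / _MAD_SCALE
    return k_sigma * sigma


def estimate_scale(subband: np.ndarray, threshold_B: float) -> float:
    """Laplacian scale ``b``: mean excess ``mean(|theta| - B)`` over the
    coefficients with ``|theta| >= B``; falls back to ``mean(|theta|)`` when
    none exceeds the threshold.  Clamped below by a small positive floor."""
    a = np.abs(np.asarray(subband)).ravel()
    if a.size == 0:
        return SCALE_FLOOR
    exceed = a[a >= threshold_B]
    b = float(np.mean(exceed - threshold_B)) if exceed.size else float(np.mean(a))
    return max(b, SCALE_FLOOR)


def threshold_labels(subband: np.ndarray, threshold_B: float) -> np.ndarray:
    """Per-coefficient thresholding labels: +1 iff ``|theta| >= B``."""
    return np.where(np.abs(subband) >= threshold_B, 1, -1).astype(np.int8)


def init_support(theta: WaveletCoefficients, threshold_B: float):
    """Warm-start support per detail subband by direct thresholding."""
    return {(s, o): SupportField(threshold_labels(a, threshold_B))
            for s, o, a in theta.detail_subbands()}


# --------------------------------------------------------------------------
# energies


def mrf_energy(s: SupportField | np.ndarray, params: MRFParams) -> float:
    """Prior energy ``H(s)`` with pair cliques of the 8-neighborhood, each
    counted once (h: (0,1), v: (1,0), d1: (1,1), d2: (1,-1) displacements)."""
    labels = s.labels if isinstance(s, SupportField) else np.asarray(s)
    labels = labels.astype(np.float64)
    e = params.alpha * labels.sum()
    e -= params.beta_h * np.sum(labels[:, 1:] * labels[:, :-1])
    e -= params.beta_v * np.sum(labels[1:, :] * labels[:-1, :])
    e -= params.beta_d1 * np.sum(labels[1:, 1:] * labels[:-1, :-1])
    e -= params.beta_d2 * np.sum(labels[1:, :-1] * labels[:-1, 1:])
    return float(e)


def _data_costs(subband, lap: LaplacianParams, gamma: float) -> np.ndarray:
    """Per-site data energies for labels -1 (index 0) and +1 (index 1).

    The label-consistent cost is the Laplacian penalty ``|theta|/b``; the
    truncation-violating label costs the finite penalty ``gamma`` instead.
    """
    a = np.abs(np.asarray(subband))
    base = lap.rate * a
    sig = a >= lap.threshold_B
    cost = np.empty(a.shape + (2,), dtype=np.float64)
    cost[..., 0] = np.where(sig, gamma, base)   # label -1
    cost[..., 1] = np.where(sig, base, gamma)   # label +1
    return cost


def default_gamma(subband, lap: LaplacianParams) -> float:
    """Finite disagreement penalty: 10x the largest data energy."""
    a = np.abs(np.asarray(subband))
    g = 10.0 * lap.rate * float(a.max()) if a.size else 0.0
    return max(g, 1.0)


def posterior_energy(s, subband, lap: LaplacianParams, params: MRFParams,
                     gamma: float | None = None) -> float:
    """Joint energy ``sum_i D_i(s_i) + H(s)`` minimized by MAP support."""
    labels = s.labels if isinstance(s, SupportField) else np.asarray(s)
    if gamma is None:
        gamma = default_gamma(subband, lap)
    dcost = _data_costs(subband, lap, gamma)
    return _metropolis.total_energy(labels, dcost, params.alpha, params.betas,
                                    params.temperature)


def map_support(subband, lap: LaplacianParams, params: MRFParams,
                s_init: SupportField | None = None, n_sweeps: int = 3,
                seed=None, gamma: float | None = None):
    """MAP support estimation by raster-scan Metropolis sampling.

    Runs ``n_sweeps`` sweeps of single-site flips at temperature ``T`` over
    the posterior energy and returns ``(SupportField, best_energy)`` for the
    lowest-energy configuration visited.  ``s_init`` defaults to direct
    thresholding (warm start).
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    subband = np.asarray(subband)
    if s_init is None:
        labels = threshold_labels(subband, lap.threshold_B)
    else:
        labels = s_init.labels.copy()
        if labels.shape != subband.shape:
            raise ValueError("s_init shape must match the subband shape")
    if gamma is None:
        gamma = default_gamma(subband, lap)
    dcost = _data_costs(subband, lap, gamma)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    rand = rng.random(n_sweeps * subband.size)
    best, energy = _metropolis.run_sweeps(labels, dcost, params.alpha,
                                          params.betas, params.temperature,
                                          rand)
    return SupportField(best), float(energy)


# --------------------------------------------------------------------------
# data-driven MRF parameters


def estimate_mrf_params(subband, s: SupportField,
                        temperature: float = 1.0) -> MRFParams:
    """Estimate ``(alpha, beta_o)`` from the significant coefficients.

    ``theta_S`` keeps the coefficients labeled significant and zeroes the
    rest.  The interaction strength per orientation is the lag-1 correlation
    of squared magnitudes ``r(i,j) = sum |theta_S(k,l)|^2 |theta_S(k+i,l+j)|^2``
    (lattice-truncated sums), normalized to unit l2 norm across the four
    orientations.  The bias is ``alpha = ||theta_S||_2^2 / (N ||theta_S||_max^2)``.

    Degenerate cases: an all-zero ``theta_S`` returns ``beta = (1/2,..)`` and
    ``alpha = 0``; a field with no co-occurring significant pairs keeps the
    uniform betas.
    """
    subband = np.asarray(subband)
    labels = s.labels if isinstance(s, SupportField) else np.asarray(s)
    if labels.shape != subband.shape:
        raise ValueError("support shape must match the subband shape")
    m = np.where(labels == 1, np.abs(subband) ** 2, 0.0)
    if not np.any(m):
        return MRFParams(0.0, 0.5, 0.5, 0.5, 0.5, temperature)
    r_d1 = float(np.sum(m[1:, 1:] * m[:-1, :-1]))
    r_h = float(np.sum(m[:, 1:] * m[:, :-1]))
    r_d2 = float(np.sum(m[1:, :-1] * m[:-1, 1:]))
    r_v = float(np.sum(m[1:, :] * m[:-1, :]))
    R = np.array([r_h, r_v, r_d1, r_d2])
    norm = float(np.linalg.norm(R))
    if norm > 0:
        bh, bv, bd1, bd2 = (R / norm).tolist()
    else:
        bh = bv = bd1 = bd2 = 0.5
    alpha = float(m.sum() / (m.size * m.max()))
    return MRFParams(alpha, bh, bv, bd1, bd2, temperature)
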