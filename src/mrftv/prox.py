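"""Proximal maps of the composite prior.

``prox_mrf`` is the support-conditioned soft-thresholding rule that solves,
component-wise and in closed form,

    argmin_theta  b|theta| + (1/(2 mu)) (theta - theta_g)^2
    subject to    |theta| >= B  (label +1)   or   |theta| <= B  (label -1).

With ``t = mu * b`` the rule is

    label +1:  B sgn(theta_g)        if |theta_g| <= t + B
               theta_g - t sgn(..)   otherwise
    label -1:  0                     if |theta_g| <= t
               theta_g - t sgn(..)   if t < |theta_g| <= t + B
               B sgn(theta_g)        if |theta_g| > t + B

It is odd, continuous in ``theta_g`` for each fixed label, and degenerates to
classical soft-thresholding for label +1 when ``B = 0``.  For complex input
the rule acts on the magnitude and preserves the phase.

``prox_tv`` approximates the isotropic total-variation proximal map with
Chambolle's dual projection algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ProxConfig", "prox_mrf", "prox_tv", "tv_norm",
           "average_prox_outputs"]


@dataclass
class ProxConfig:
    """Step and regularization weights for the two proximal maps."""

    mu: float = 1.0
    tau1: float = 1.0
    tau2: float = 1.0
    tv_inner_iters: int = 20

    def __post_init__(self):
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.tau1 < 0 or self.tau2 < 0:
            raise ValueError("tau1 and tau2 must be nonnegative")
        if self.tv_inner_iters < 1:
            raise ValueError("tv_inner_iters must be >= 1")


def prox_mrf(theta_g, s_hat, threshold_B: float, scale_b: float,
             mu: float = 1.0):
    """Support-conditioned soft-thresholding (see module docstring).

    Parameters
    ----------
    theta_g : array_like
        Subband coefficients (real or complex) at which the prox is evaluated.
    s_hat : array_like of {-1, +1}
        MAP support labels for the subband.
    threshold_B, scale_b : float
        Truncated-Laplacian parameters ``B`` and ``b``.
    mu : float
        Effective step (already includes the regularization weight tau1).
    """
    theta_g = np.asarray(theta_g)
    labels = np.asarray(s_hat.labels if hasattr(s_hat, "labels") else s_hat)
    if labels.shape != theta_g.shape:
        raise ValueError("support shape must match the coefficient shape")
    B = float(threshold_B)
    t = float(mu) * float(scale_b)
    mag = np.abs(theta_g)
    if np.iscomplexobj(theta_g):
        sgn = np.where(mag > 0, theta_g / np.where(mag > 0, mag, 1.0), 0.0)
    else:
        sgn = np.sign(theta_g)
    clamp = np.full_like(mag, B)
    pos = np.where(mag <= t + B, clamp, mag - t)
    neg = np.where(mag <= t, 0.0, np.where(mag <= t + B, mag - t, clamp))
    return np.where(labels == 1, pos, neg) * sgn


def tv_norm(x) -> float:
    """Isotropic TV: ``sum sqrt(|dx|^2 + |dy|^2)`` with zero-padded forward
    differences at the lattice boundary."""
    x = np.asarray(x)
    gx = np.zeros_like(x, dtype=float)
    gy = np.zeros_like(x, dtype=float)
    gx[:-1, :] = np.abs(np.diff(x, axis=0)) ** 2
    gy[:, :-1] = np.abs(np.diff(x, axis=1)) ** 2
    return float(np.sum(np.sqrt(gx + gy)))


def _grad(u):
    gx = np.zeros_like(u)
    gy = np.zeros_like(u)
    gx[:-1, :] = u[1:, :] - u[:-1, :]
    gy[:, :-1] = u[:, 1:] - u[:, :-1]
    return gx, gy


def _div(px, py):
    d = np.zeros_like(px)
    d[0, :] += px[0, :]
    d[1:-1, :] += px[1:-1, :] - px[:-2, :]
    d[-1, :] -= px[-2, :]
    d[:, 0] += py[:, 0]
    d[:, 1:-1] += py[:, 1:-1] - py[:, :-2]
    d[:, -1] -= py[:, -2]
    return d


def _prox_tv_real(f, lam, iters, tau):
    if lam <= 0:
        return f.copy()
    px = np.zeros_like(f)
    py = np.zeros_like(f)
    for _ in range(iters):
        gx, gy = _grad(_div(px, py) - f / lam)
        denom = 1.0 + tau * np.sqrt(gx ** 2 + gy ** 2)
        px = (px + tau * gx) / denom
        py = (py + tau * gy) / denom
    return f - lam * _div(px, py)


def prox_tv(xg, weight: float, iters: int = 20, tau: float = 0.248):
    """Approximate ``argmin_x weight*||x||_TV + 0.5*||x - xg||^2`` by
    Chambolle's dual projection with ``iters`` inner iterations.

    Complex input is handled by applying the map separately to the real and
    imaginary parts.
    """
    if weight < 0:
        raise ValueError("weight must be >= 0")
    if iters < 1:
        raise ValueError("iters must be >= 1")
    xg = np.asarray(xg)
    if np.iscomplexobj(xg):
        return (_prox_tv_real(xg.real.astype(float), weight, iters, tau)
                + 1j * _prox_tv_real(xg.imag.astype(float), weight, iters, tau))
    return _prox_tv_real(xg.astype(float), weight, iters, tau)


def average_prox_outputs(x1, x2):
    """Pointwise mean of the two proximal outputs."""
    x1 = np.asarray(x1)
    x2 = np.asarray(x2)
    if x1.shape != x2.shape:
        raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
    return (x1 + x2) / 2.0
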