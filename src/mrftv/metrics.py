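"""Reconstruction quality metrics: PSNR, SSIM and relative l2-norm error.

All three operate on image magnitudes; complex inputs are magnitude-reduced
first.  ``max_mr`` is the maximum of the image dynamic range (255 for the
standard [0, 255] convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["MetricReport", "psnr", "ssim", "rlne", "evaluate"]


@dataclass
class MetricReport:
    psnr_db: float
    ssim: float
    rlne: float
    max_mr: float

    def to_json(self, **kwargs) -> str:
        return json.dumps(asdict(self), **kwargs)


def _mag(x):
    x = np.asarray(x)
    return np.abs(x) if np.iscomplexobj(x) else x.astype(float)


def _check_pair(a, b):
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def psnr(x_hat, x_ref, max_mr: float = 255.0) -> float:
    """Peak signal-to-noise ratio ``10 log10(max_mr^2 / MSE)`` in dB.

    Identical images (zero MSE) return ``inf``.
    """
    if max_mr <= 0:
        raise ValueError("max_mr must be positive")
    a, b = _mag(x_hat), _mag(x_ref)
    _check_pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(max_mr ** 2 / mse)


def ssim(x_hat, x_ref, max_mr: float = 255.0) -> float:
    """Mean structural similarity index.

    Local statistics use an isotropic Gaussian window with sigma = 1.5
    (11x11 truncated support) and the stabilization constants
    ``C1 = (0.01 max_mr)^2``, ``C2 = (0.03 max_mr)^2``.
    """
    a, b = _mag(x_hat), _mag(x_ref)
    _check_pair(a, b)
    return float(structural_similarity(
        a, b, data_range=max_mr, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def rlne(x_hat, x_ref) -> float:
    """Relative l2-norm error ``||x_hat - x_ref||_2 / ||x_ref||_2``."""
    a, b = _mag(x_hat), _mag(x_ref)
    _check_pair(a, b)
    denom = float(np.linalg.norm(b))
    if denom == 0.0:
        raise ValueError("reference image must not be identically zero")
    return float(np.linalg.norm(a - b)) / denom


def evaluate(x_hat, x_ref, max_mr: float = 255.0) -> MetricReport:
    """All three metrics in one report."""
    return MetricReport(psnr_db=psnr(x_hat, x_ref, max_mr),
                        ssim=ssim(x_hat, x_ref, max_mr),
                        rlne=rlne(x_hat, x_ref),
                        max_mr=float(max_mr))
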