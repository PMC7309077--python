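"""Synthetic phantoms, coil maps and measurement noise.

These generators emulate the input classes the reconstruction consumes:
piecewise-smooth anatomical magnitude images (optionally with band-limited
texture), smooth complex phase, smooth per-coil sensitivity profiles with a
unit sum-of-squares, and i.i.d. circular complex Gaussian measurement noise.
Everything is bit-reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .operators import KSpaceData
from .sampling import SamplingMask

__all__ = ["PhantomSpec", "make_phantom", "make_coil_maps", "add_noise",
           "simulate_measurements"]

_KINDS = ("shepp_logan", "piecewise_texture", "complex_phase")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic test image.

    ``texture_amplitude`` scales the band-limited texture added inside the
    piecewise-smooth regions (in intensity units of the [0, max_mr] range);
    ``phase_smoothness`` divides the low-order polynomial phase, so larger
    values mean flatter phase (infinite -> purely real image).
    """

    shape: tuple = (128, 128)
    kind: str = "piecewise_texture"
    texture_amplitude: float = 20.0
    phase_smoothness: float = 1.0
    max_mr: float = 255.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown phantom kind: {self.kind!r}")


def _shepp_logan(shape, max_mr):
    img = shepp_logan_phantom()  # 400x400 in [0, 1]
    img = resize(img, shape, order=1, anti_aliasing=True)
    return np.clip(img, 0, 1) * max_mr


def _piecewise_texture(shape, amplitude, max_mr, rng):
    # piecewise-constant regions from thresholded smoothed noise
    base_field = ndimage.gaussian_filter(rng.normal(size=shape),
                                         sigma=min(shape) / 10.0)
    levels = np.quantile(base_field, [0.25, 0.5, 0.75])
    region = np.digitize(base_field, levels)
    values = np.array([0.15, 0.45, 0.7, 0.95]) * max_mr
    img = values[region]
    # circular support so the object has a background, as anatomy does
    rr, cc = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    cr, cc0 = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    support = np.hypot((rr - cr) / shape[0], (cc - cc0) / shape[1]) < 0.45
    img = img * support
    if amplitude > 0:
        # band-limited texture: difference of Gaussian-smoothed white noise
        w = rng.normal(size=shape)
        tex = ndimage.gaussian_filter(w, 1.0) - ndimage.gaussian_filter(w, 3.0)
        tex /= max(np.abs(tex).max(), 1e-12)
        img = img + amplitude * tex * support
    return np.clip(img, 0, max_mr)


def _smooth_phase(shape, smoothness, rng):
    rr, cc = np.meshgrid(*(np.linspace(-1, 1, s) for s in shape), indexing="ij")
    c = rng.uniform(-1, 1, size=6)
    poly = (c[0] + c[1] * rr + c[2] * cc + c[3] * rr * cc
            + c[4] * rr ** 2 + c[5] * cc ** 2)
    return np.pi * poly / max(smoothness, 1e-12)


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate the phantom described by ``spec`` (complex ndarray).

    ``shepp_logan`` is the classic ellipse phantom; ``piecewise_texture``
    combines random piecewise-constant regions with band-limited texture;
    ``complex_phase`` multiplies the textured magnitude by a smooth
    low-order polynomial phase.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "shepp_logan":
        mag = _shepp_logan(spec.shape, spec.max_mr)
        return mag.astype(complex)
    mag = _piecewise_texture(spec.shape, spec.texture_amplitude, spec.max_mr,
                             rng)
    if spec.kind == "piecewise_texture":
        return mag.astype(complex)
    phase = _smooth_phase(spec.shape, spec.phase_smoothness, rng)
    return mag * np.exp(1j * phase)


def make_coil_maps(shape, n_coils: int, seed: int | None = None):
    """Smooth complex coil sensitivity maps with unit sum of squares.

    Coil centers sit on a circle around the image center (for 4 coils, one
    per quadrant).  A single coil yields the constant unit map.
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    if n_coils == 1:
        return [np.ones(shape, dtype=complex)]
    rng = np.random.default_rng(seed)
    rr, cc = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    cr, cc0 = (shape[0] - 1) / 2, (shape[1] - 1) / 2
    radius = 0.35 * min(shape)
    width = 0.6 * min(shape)
    maps = []
    for i in range(n_coils):
        ang = 2 * np.pi * (i + 0.5) / n_coils
        kr = cr + radius * np.sin(ang)
        kc = cc0 + radius * np.cos(ang)
        g = np.exp(-((rr - kr) ** 2 + (cc - kc) ** 2) / (2 * width ** 2))
        # gentle smooth phase, distinct per coil
        ph = rng.uniform(-0.5, 0.5) * (rr / shape[0]) \
            + rng.uniform(-0.5, 0.5) * (cc / shape[1])
        maps.append(g * np.exp(1j * np.pi * ph))
    sos = np.sqrt(sum(np.abs(c) ** 2 for c in maps))
    return [c / sos for c in maps]


def add_noise(y: np.ndarray, sigma: float, seed: int | None = None):
    """Add i.i.d. circular complex Gaussian noise, std ``sigma`` per
    real/imaginary component."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    y = np.asarray(y, dtype=complex)
    if sigma == 0:
        return y.copy()
    rng = np.random.default_rng(seed)
    return y + sigma * (rng.standard_normal(y.shape)
                        + 1j * rng.standard_normal(y.shape))


def simulate_measurements(image: np.ndarray, mask: SamplingMask,
                          sensitivities=None, sigma: float = 0.0,
                          seed: int | None = None) -> KSpaceData:
    """Forward-simulate undersampled (optionally multi-coil, noisy) k-space
    data from a ground-truth image."""
    data = KSpaceData(y=np.zeros((1 if sensitivities is None
                                  else len(sensitivities), mask.n_samples),
                                 dtype=complex),
                      mask=mask, sensitivities=sensitivities)
    y = data.forward(np.asarray(image, dtype=complex))
    return KSpaceData(y=add_noise(y, sigma, seed), mask=mask,
                      sensitivities=sensitivities)
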