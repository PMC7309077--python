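"""Linear measurement and representation operators.

The measurement operator is the partially observed orthonormal 2-D DFT
(``A`` / ``A^H``); the multi-coil composite operator multiplies by the coil
sensitivity map before the Fourier transform (``y_i = A C_i x``) and its
adjoint accumulates ``sum_i conj(C_i) A^H y_i``.  The sparsifying transform is
the non-decimated (stationary) separable wavelet frame ``W`` with unit-energy
normalization, so that ``W^H W = I`` and ``W^H`` is the exact adjoint.

The DFT uses orthonormal scaling (``1/sqrt(N)`` each direction), which makes
the data-fidelity gradient step non-expansive for step sizes ``mu <= 1``.
Masks are defined on the DC-centered grid; this module owns the fftshift
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .sampling import SamplingMask

__all__ = [
    "KSpaceData",
    "WaveletCoefficients",
    "fourier_forward",
    "fourier_adjoint",
    "multicoil_forward",
    "multicoil_adjoint",
    "wavelet_analysis",
    "wavelet_synthesis",
]


# --------------------------------------------------------------------------
# measurement container


@dataclass
class KSpaceData:
    """Undersampled k-space measurements.

    Attributes
    ----------
    y : complex ndarray, shape (n_coils, M)
        One measurement block per coil, each of length ``mask.n_samples``,
        in raster (row-major) order over the true mask positions.
    mask : SamplingMask
    sensitivities : list of complex ndarray, optional
        Per-coil maps ``C_i``, each with the image shape.
    """

    y: np.ndarray
    mask: SamplingMask
    sensitivities: list[np.ndarray] | None = None

    def __post_init__(self):
        y = np.atleast_2d(np.asarray(self.y, dtype=complex))
        self.y = y
        M = self.mask.n_samples
        if y.shape[1] != M:
            raise ValueError(
                f"each measurement block must have {M} entries, got {y.shape[1]}")
        if self.sensitivities is not None:
            maps = [np.asarray(c, dtype=complex) for c in self.sensitivities]
            if len(maps) != y.shape[0]:
                raise ValueError("sensitivity count must equal the coil count")
            for c in maps:
                if c.shape != self.mask.shape:
                    raise ValueError("each coil map must have the image shape")
            self.sensitivities = maps

    @property
    def n_coils(self) -> int:
        return self.y.shape[0]

    @property
    def shape(self):
        return self.mask.shape

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Apply the configured measurement operator (single- or multi-coil)."""
        if self.sensitivities is None:
            return fourier_forward(x, self.mask)[None, :]
        return multicoil_forward(x, self.sensitivities, self.mask)

    def adjoint(self, y_blocks: np.ndarray) -> np.ndarray:
        if self.sensitivities is None:
            return fourier_adjoint(np.asarray(y_blocks).reshape(-1), self.mask)
        return multicoil_adjoint(y_blocks, self.sensitivities, self.mask)


# --------------------------------------------------------------------------
# masked Fourier operators


def fourier_forward(x: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """``A x``: orthonormal 2-D DFT of ``x`` sampled at the mask positions."""
    x = np.asarray(x)
    if x.shape != mask.shape:
        raise ValueError(f"image shape {x.shape} != mask shape {mask.shape}")
    ksp = np.fft.fftshift(np.fft.fft2(x, norm="ortho"))
    return ksp[mask.grid]


def fourier_adjoint(y: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """``A^H y``: zero-fill onto the grid, inverse orthonormal DFT."""
    y = np.asarray(y, dtype=complex).reshape(-1)
    if y.size != mask.n_samples:
        raise ValueError(
            f"measurement length {y.size} != mask sample count {mask.n_samples}")
    grid = np.zeros(mask.shape, dtype=complex)
    grid[mask.grid] = y
    return np.fft.ifft2(np.fft.ifftshift(grid), norm="ortho")


def multicoil_forward(x, sensitivities, mask: SamplingMask) -> np.ndarray:
    """Stacked per-coil measurements ``y_i = A (C_i * x)``, coil-major."""
    if not sensitivities:
        raise ValueError("sensitivities must be non-empty")
    return np.stack([fourier_forward(c * x, mask) for c in sensitivities])


def multicoil_adjoint(y_blocks, sensitivities, mask: SamplingMask) -> np.ndarray:
    """``M^H y = sum_i conj(C_i) * A^H y_i``."""
    y_blocks = np.atleast_2d(np.asarray(y_blocks, dtype=complex))
    if len(sensitivities) != y_blocks.shape[0]:
        raise ValueError("block count must equal sensitivity count")
    out = np.zeros(mask.shape, dtype=complex)
    for c, y in zip(sensitivities, y_blocks):
        out += np.conj(c) * fourier_adjoint(y, mask)
    return out


# --------------------------------------------------------------------------
# non-decimated wavelet frame


@dataclass
class WaveletCoefficients:
    """Non-decimated wavelet coefficients with subband bookkeeping.

    ``approx`` is the coarsest-scale LL subband; ``details[s]`` is a dict
    with orientations ``'LH'`` (horizontal detail), ``'HL'`` (vertical
    detail) and ``'HH'`` (diagonal detail) at scale ``s+1`` (scale 1 =
    finest).  Every subband has the full image shape.
    """

    approx: np.ndarray
    details: list[dict[str, np.ndarray]]
    wavelet: str
    image_shape: tuple = field(default=None)

    def __post_init__(self):
        if self.image_shape is None:
            self.image_shape = tuple(self.approx.shape)

    @property
    def scales(self) -> int:
        return len(self.details)

    def detail_subbands(self):
        """Iterate ``(scale, orientation, array)`` over detail subbands,
        finest scale first."""
        for s, d in enumerate(self.details, start=1):
            for o in ("LH", "HL", "HH"):
                yield s, o, d[o]

    @property
    def finest_diagonal(self) -> np.ndarray:
        """The finest-scale diagonal (HH1) subband, used for noise estimation."""
        return self.details[0]["HH"]

    def copy(self) -> "WaveletCoefficients":
        return WaveletCoefficients(
            self.approx.copy(),
            [{o: a.copy() for o, a in d.items()} for d in self.details],
            self.wavelet, self.image_shape)


_ORIENTS = ("LH", "HL", "HH")


def _swt_real(x, wavelet, scales):
    coeffs = pywt.swt2(x, wavelet, level=scales, norm=True, trim_approx=True)
    approx = coeffs[0]
    # pywt returns coarsest detail first; reorder finest-first
    details = []
    for tup in reversed(coeffs[1:]):
        cH, cV, cD = tup
        details.append({"LH": cH, "HL": cV, "HH": cD})
    return approx, details


def wavelet_analysis(x: np.ndarray, wavelet: str = "db4",
                     scales: int = 3) -> WaveletCoefficients:
    """``W x``: undecimated separable wavelet frame (Parseval-normalized)."""
    x = np.asarray(x)
    if scales < 1:
        raise ValueError("scales must be >= 1")
    if min(x.shape) < 2 ** scales or any(s % 2 ** scales for s in x.shape):
        raise ValueError(
            f"image shape {x.shape} incompatible with {scales} stationary "
            f"scales (each dimension must be a multiple of {2 ** scales})")
    if np.iscomplexobj(x):
        ar, dr = _swt_real(x.real, wavelet, scales)
        ai, di = _swt_real(x.imag, wavelet, scales)
        approx = ar + 1j * ai
        details = [{o: dr[s][o] + 1j * di[s][o] for o in _ORIENTS}
                   for s in range(scales)]
    else:
        approx, details = _swt_real(x, wavelet, scales)
    return WaveletCoefficients(approx, details, wavelet, tuple(x.shape))


def _iswt_real(approx, details, wavelet):
    coeffs = [approx] + [(d["LH"], d["HL"], d["HH"]) for d in reversed(details)]
    return pywt.iswt2(coeffs, wavelet, norm=True)


def wavelet_synthesis(theta: WaveletCoefficients) -> np.ndarray:
    """``W^H theta``: adjoint synthesis; exact left inverse of the analysis."""
    cplx = np.iscomplexobj(theta.approx) or any(
        np.iscomplexobj(a) for _, _, a in theta.detail_subbands())
    if cplx:
        re = _iswt_real(np.real(theta.approx),
                        [{o: np.real(a) for o, a in d.items()}
                         for d in theta.details], theta.wavelet)
        im = _iswt_real(np.imag(theta.approx),
                        [{o: np.imag(a) for o, a in d.items()}
                         for d in theta.details], theta.wavelet)
        return re + 1j * im
    return _iswt_real(theta.approx, theta.details, theta.wavelet)
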