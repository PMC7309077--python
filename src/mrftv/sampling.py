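"""Cartesian k-space undersampling trajectories.

All masks live on the *centered* k-space grid (DC at ``(n//2, m//2)``); the
operator module handles the FFT shift convention.  Every generator records the
achieved sampling fraction exactly and is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SamplingMask",
    "radial_mask",
    "vertical_lines_mask",
    "random_mask",
    "uniform_mask",
    "golden_ratio_line_subset",
    "GOLDEN_ANGLE_DEG",
]

#: Azimuthal gap of the golden-ratio radial profile ordering, in degrees.
GOLDEN_ANGLE_DEG = 111.246


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space sampling pattern.

    Attributes
    ----------
    grid : ndarray of bool
        True where the k-space sample is acquired (DC-centered layout).
    rate : float
        Achieved sampling fraction, exactly ``grid.sum() / grid.size``.
    kind : str
        One of ``radial``, ``random``, ``vertical_lines``, ``uniform``,
        ``full``.
    """

    grid: np.ndarray
    kind: str
    rate: float = field(init=False)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "rate", float(grid.sum()) / grid.size)

    @property
    def shape(self):
        return self.grid.shape

    @property
    def n_samples(self) -> int:
        return int(self.grid.sum())


def _check_shape(shape):
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise ValueError(f"shape must have two positive dimensions, got {shape}")
    return int(shape[0]), int(shape[1])


def _center(shape):
    return shape[0] // 2, shape[1] // 2


def full_mask(shape) -> SamplingMask:
    n, m = _check_shape(shape)
    return SamplingMask(np.ones((n, m), dtype=bool), kind="full")


def radial_mask(shape, n_lines: int, seed: int | None = None,
                randomize_start: bool = False) -> SamplingMask:
    """Union of ``n_lines`` straight lines through the k-space center.

    Angles are equispaced on [0, pi) starting at 0; ``seed`` only perturbs the
    starting angle when ``randomize_start`` is set.  Lines are rasterized with
    nearest-neighbor (Bresenham-style) stepping; the DC sample is always
    included.
    """
    n, m = _check_shape(shape)
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    offset = 0.0
    if randomize_start:
        offset = np.random.default_rng(seed).uniform(0.0, np.pi / n_lines)
    grid = np.zeros((n, m), dtype=bool)
    cr, cc = _center((n, m))
    half = max(n, m)  # long enough to leave the grid in every direction
    for k in range(n_lines):
        ang = offset + np.pi * k / n_lines
        dr, dc = np.sin(ang), np.cos(ang)
        # sample the line at unit steps and round: nearest-neighbor raster
        t = np.arange(-half, half + 1)
        rr = np.rint(cr + t * dr).astype(int)
        cc_ = np.rint(cc + t * dc).astype(int)
        ok = (rr >= 0) & (rr < n) & (cc_ >= 0) & (cc_ < m)
        grid[rr[ok], cc_[ok]] = True
    grid[cr, cc] = True
    return SamplingMask(grid, kind="radial")


def radial_mask_for_rate(shape, rate: float, seed: int | None = None) -> SamplingMask:
    """Radial mask whose achieved rate is as close as possible to ``rate``.

    Searches the monotone-in-``n_lines`` achieved rate by bisection.
    """
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    n, m = _check_shape(shape)
    lo, hi = 1, 4 * max(n, m)
    best = None
    while lo <= hi:
        mid = (lo + hi) // 2
        cand = radial_mask(shape, mid, seed)
        if best is None or abs(cand.rate - rate) < abs(best.rate - rate):
            best = cand
        if cand.rate < rate:
            lo = mid + 1
        else:
            hi = mid - 1
    return best


def vertical_lines_mask(shape, rate: float, n_center_lines: int = 0,
                        seed: int | None = None) -> SamplingMask:
    """Full k-space columns: a contiguous low-frequency block plus random
    outer columns until ``round(rate * width)`` columns are selected."""
    n, m = _check_shape(shape)
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    n_cols = int(round(rate * m))
    n_cols = max(n_cols, 1)
    if n_center_lines > n_cols:
        raise ValueError(
            f"rate {rate} too small for {n_center_lines} center lines")
    cc = m // 2
    lo = cc - (n_center_lines - 1) // 2
    center_cols = list(range(lo, lo + n_center_lines))
    outer = [c for c in range(m) if c not in center_cols]
    rng = np.random.default_rng(seed)
    extra = rng.choice(len(outer), size=n_cols - n_center_lines, replace=False)
    cols = np.asarray(center_cols + [outer[i] for i in extra], dtype=int)
    grid = np.zeros((n, m), dtype=bool)
    grid[:, cols] = True
    return SamplingMask(grid, kind="vertical_lines")


def random_mask(shape, rate: float, density: str = "variable",
                seed: int | None = None) -> SamplingMask:
    """Pointwise pseudo-random mask with an exact sample count.

    ``density='uniform'`` draws ``round(rate*N)`` entries uniformly without
    replacement; ``density='variable'`` concentrates samples near the k-space
    center with probability proportional to ``(1 + r/r0)^(-2)``,
    ``r0 = (grid half-width)/8``.  The DC sample is always included.
    """
    n, m = _check_shape(shape)
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    if density not in ("uniform", "variable"):
        raise ValueError(f"unknown density law: {density}")
    total = n * m
    k = int(round(rate * total))
    k = max(k, 1)
    cr, cc = _center((n, m))
    dc_flat = cr * m + cc
    if k == total:
        return SamplingMask(np.ones((n, m), dtype=bool), kind="random")
    rng = np.random.default_rng(seed)
    others = np.delete(np.arange(total), dc_flat)
    if density == "uniform":
        chosen = rng.choice(others, size=k - 1, replace=False)
    else:
        rr, cc_ = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
        r = np.hypot(rr - cr, cc_ - cc).ravel()[others]
        r0 = max(n, m) / 2.0 / 8.0
        w = (1.0 + r / r0) ** -2.0
        w /= w.sum()
        chosen = rng.choice(others, size=k - 1, replace=False, p=w)
    flat = np.zeros(total, dtype=bool)
    flat[dc_flat] = True
    flat[chosen] = True
    return SamplingMask(flat.reshape(n, m), kind="random")


def uniform_mask(shape, rate: float) -> SamplingMask:
    """Deterministic regular-lattice undersampling at approximately ``rate``.

    Keeps every ``s``-th row and column with strides chosen so the kept
    fraction is as close as possible to ``rate``; DC always included.
    """
    n, m = _check_shape(shape)
    if not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    best = None
    for sr in range(1, n + 1):
        for sc in range(1, m + 1):
            frac = (len(range(0, n, sr)) * len(range(0, m, sc))) / (n * m)
            err = abs(frac - rate)
            if best is None or err < best[0]:
                best = (err, sr, sc)
            if frac < rate:
                break  # increasing sc only lowers the fraction further
    _, sr, sc = best
    grid = np.zeros((n, m), dtype=bool)
    cr, cc = _center((n, m))
    rows = (cr + np.arange(0, n, sr)) % n
    cols = (cc + np.arange(0, m, sc)) % m
    grid[np.ix_(np.unique(rows), np.unique(cols))] = True
    grid[cr, cc] = True
    return SamplingMask(grid, kind="uniform")


def golden_ratio_line_subset(available_angles, target_rate: float):
    """Golden-ratio ordered subset of radial line angles.

    Starting from the first available angle, repeatedly advance by the golden
    azimuthal gap of 111.246 degrees (mod 360) from the previously *selected*
    position and snap to the nearest available, not-yet-selected angle, until
    ``round(target_rate * n_available)`` lines are selected.  Returns the
    selected angles in selection order.
    """
    angles = np.asarray(list(available_angles), dtype=float)
    if angles.size == 0:
        raise ValueError("available_angles must be non-empty")
    if np.any((angles < 0) | (angles >= 360)):
        raise ValueError("angles must lie in [0, 360)")
    if not 0 < target_rate <= 1:
        raise ValueError("target_rate must be in (0, 1]")
    n_sel = int(round(target_rate * angles.size))
    n_sel = max(n_sel, 1)
    free = np.ones(angles.size, dtype=bool)
    order = []
    idx = 0  # start from the first listed line
    free[idx] = False
    order.append(idx)
    pos = angles[idx]
    for _ in range(n_sel - 1):
        pos = (pos + GOLDEN_ANGLE_DEG) % 360.0
        d = np.abs(angles - pos)
        d = np.minimum(d, 360.0 - d)  # circular distance
        d[~free] = np.inf
        idx = int(np.argmin(d))
        free[idx] = False
        order.append(idx)
        pos = angles[idx]
    return [float(angles[i]) for i in order]
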