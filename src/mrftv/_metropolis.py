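"""Raster-scan Metropolis sweeps for the anisotropic Ising support model.

The kernel is compiled with numba when available; a pure-Python fallback with
identical semantics (same visitation order, same random-number consumption) is
used otherwise, so results are bit-identical across both paths.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _total_energy(labels, dcost, alpha, bh, bv, bd1, bd2):
    n, m = labels.shape
    e = 0.0
    for i in range(n):
        for j in range(m):
            s = labels[i, j]
            e += dcost[i, j, (s + 1) // 2] + alpha * s
            # pair cliques counted once: right, down, down-right, down-left
            if j + 1 < m:
                e -= bh * s * labels[i, j + 1]
            if i + 1 < n:
                e -= bv * s * labels[i + 1, j]
            if i + 1 < n and j + 1 < m:
                e -= bd1 * s * labels[i + 1, j + 1]
            if i + 1 < n and j - 1 >= 0:
                e -= bd2 * s * labels[i + 1, j - 1]
    return e


@njit(cache=True)
def _neighbor_field(labels, i, j, bh, bv, bd1, bd2):
    n, m = labels.shape
    h = 0.0
    if j - 1 >= 0:
        h += bh * labels[i, j - 1]
    if j + 1 < m:
        h += bh * labels[i, j + 1]
    if i - 1 >= 0:
        h += bv * labels[i - 1, j]
    if i + 1 < n:
        h += bv * labels[i + 1, j]
    if i - 1 >= 0 and j - 1 >= 0:
        h += bd1 * labels[i - 1, j - 1]
    if i + 1 < n and j + 1 < m:
        h += bd1 * labels[i + 1, j + 1]
    if i - 1 >= 0 and j + 1 < m:
        h += bd2 * labels[i - 1, j + 1]
    if i + 1 < n and j - 1 >= 0:
        h += bd2 * labels[i + 1, j - 1]
    return h


@njit(cache=True)
def _run_sweeps(labels, dcost, alpha, bh, bv, bd1, bd2, T, rand):
    """In-place Metropolis sweeps; returns (best_labels, best_energy).

    ``dcost[i, j, k]`` holds the data energy for label -1 (k=0) and +1 (k=1);
    ``rand`` is a flat array of uniforms of length n_sweeps * n * m.
    """
    n, m = labels.shape
    energy = _total_energy(labels, dcost, alpha, bh, bv, bd1, bd2)
    best = labels.copy()
    best_energy = energy
    n_sweeps = rand.size // (n * m)
    u = 0
    for _ in range(n_sweeps):
        for i in range(n):
            for j in range(m):
                s = labels[i, j]
                d_flip = (dcost[i, j, (1 - s) // 2]
                          - dcost[i, j, (s + 1) // 2])
                h = _neighbor_field(labels, i, j, bh, bv, bd1, bd2)
                delta = d_flip - 2.0 * alpha * s + 2.0 * s * h
                if delta <= 0.0 or rand[u] < np.exp(-delta / T):
                    labels[i, j] = -s
                    energy += delta
                    if energy < best_energy - 1e-12:
                        best_energy = energy
                        best[:, :] = labels
                u += 1
    return best, best_energy


def run_sweeps(labels, dcost, alpha, betas, T, rand):
    labels = np.ascontiguousarray(labels, dtype=np.int8)
    dcost = np.ascontiguousarray(dcost, dtype=np.float64)
    bh, bv, bd1, bd2 = (float(b) for b in betas)
    return _run_sweeps(labels, dcost, float(alpha), bh, bv, bd1, bd2,
                       float(T), np.ascontiguousarray(rand, dtype=np.float64))


def total_energy(labels, dcost, alpha, betas, T=1.0):
    labels = np.ascontiguousarray(labels, dtype=np.int8)
    dcost = np.ascontiguousarray(dcost, dtype=np.float64)
    bh, bv, bd1, bd2 = (float(b) for b in betas)
    return float(_total_energy(labels, dcost, float(alpha), bh, bv, bd1, bd2))
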