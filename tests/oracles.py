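"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (plain Python loops, conservative
convergence settings) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def hex_patch_bfs(n_shells: int) -> np.ndarray:
    """Centered hexagonal patch by breadth-first search on the triangular
    lattice: all points within ``n_shells`` unit steps of the origin."""
    step_vectors = [
        (math.cos(k * math.pi / 3.0), math.sin(k * math.pi / 3.0)) for k in range(6)
    ]
    frontier = {(0.0, 0.0)}
    seen = {(0.0, 0.0): 0}
    for depth in range(1, n_shells + 1):
        new = set()
        for (x, y) in frontier:
            for dx, dy in step_vectors:
                p = (round(x + dx, 9), round(y + dy, 9))
                if p not in seen:
                    seen[p] = depth
                    new.add(p)
        frontier = new
    return np.array(sorted(seen)), np.array([seen[tuple(p)] for p in sorted(seen)])


def ewald_reference(
    positions: np.ndarray,
    charges: np.ndarray,
    box: float,
    l_bjerrum: float,
    alpha: float,
    n_kmax: int,
    excluded_pairs=(),
) -> float:
    """Naive, loop-based Ewald sum with independently chosen parameters.

    Real-space sum over all minimum-image pairs (no cutoff), reciprocal
    sum over a full cube of k vectors, self term, and exclusion terms.
    """
    n = len(positions)
    e_real = 0.0
    excluded = {tuple(sorted(p)) for p in excluded_pairs}
    for i in range(n):
        for j in range(i + 1, n):
            d = positions[i] - positions[j]
            d -= box * np.round(d / box)
            r = math.sqrt(float(d @ d))
            if (i, j) in excluded:
                e_real -= l_bjerrum * charges[i] * charges[j] * math.erf(alpha * r) / r
            else:
                e_real += l_bjerrum * charges[i] * charges[j] * math.erfc(alpha * r) / r
    volume = box**3
    e_rec = 0.0
    for nx in range(-n_kmax, n_kmax + 1):
        for ny in range(-n_kmax, n_kmax + 1):
            for nz in range(-n_kmax, n_kmax + 1):
                if nx == 0 and ny == 0 and nz == 0:
                    continue
                k = 2.0 * math.pi / box * np.array([nx, ny, nz])
                k2 = float(k @ k)
                s = complex(0.0, 0.0)
                for i in range(n):
                    s += charges[i] * np.exp(1j * float(k @ positions[i]))
                e_rec += math.exp(-k2 / (4.0 * alpha**2)) / k2 * abs(s) ** 2
    e_rec *= l_bjerrum * 2.0 * math.pi / volume
    e_self = -l_bjerrum * alpha / math.sqrt(math.pi) * float((charges**2).sum())
    return e_real + e_rec + e_self


def numerical_gradient(energy_fn, positions: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar energy function."""
    grad = np.zeros_like(positions)
    for i in range(positions.shape[0]):
        for d in range(3):
            p_plus = positions.copy()
            p_plus[i, d] += h
            p_minus = positions.copy()
            p_minus[i, d] -= h
            grad[i, d] = (energy_fn(p_plus) - energy_fn(p_minus)) / (2.0 * h)
    return grad


def rod_rg_direct(n: int, b: float) -> float:
    """Radius of gyration of n collinear points at spacing b, by direct
    summation over the definition."""
    x = np.arange(n) * b
    c = x - x.mean()
    return math.sqrt(float((c**2).mean()))
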