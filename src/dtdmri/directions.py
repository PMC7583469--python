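"""Deterministic direction sets on the half-sphere.

Diffusion-encoding directions are axial (u and -u are equivalent), so point
sets are optimized under antipodal symmetry: each point interacts with every
other point and with all antipodes (electrostatic repulsion).  Optimization
starts from a Fibonacci half-sphere and runs a fixed number of projected
gradient steps, so the result is a pure function of ``n`` — two calls give
bitwise-identical arrays.

The 15-direction set used by the default acquisition protocol is frozen as a
module constant (generated once by :func:`repulsion_directions`).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["repulsion_directions", "DIRECTIONS_15"]


def _fibonacci_half_sphere(n: int) -> np.ndarray:
    """Quasi-uniform start layout: n points on the upper hemisphere."""
    i = np.arange(n) + 0.5
    z = i / n  # cos(theta) in (0, 1): upper hemisphere
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    st = np.sqrt(1.0 - z**2)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), z])


def _repulsion_energy_grad(points: np.ndarray) -> np.ndarray:
    """Gradient of sum_{i<j} 1/d(ui,uj) over both each point and its antipode."""
    grad = np.zeros_like(points)
    for sign in (1.0, -1.0):
        diff = points[:, None, :] - sign * points[None, :, :]  # (n, n, 3)
        dist = np.linalg.norm(diff, axis=-1)
        np.fill_diagonal(dist, np.inf)
        grad += -(diff / dist[..., None] ** 3).sum(axis=1)
    return grad


@lru_cache(maxsize=32)
def _repulsion_directions_cached(n: int) -> np.ndarray:
    points = _fibonacci_half_sphere(n)
    if n == 1:
        out = np.array([[0.0, 0.0, 1.0]])
        out.flags.writeable = False
        return out
    step = 0.05 / n
    for _ in range(500):
        grad = _repulsion_energy_grad(points)
        # project gradient onto tangent planes and step downhill
        grad -= points * (grad * points).sum(axis=1, keepdims=True)
        points = points - step * grad
        points /= np.linalg.norm(points, axis=1, keepdims=True)
        points[points[:, 2] < 0] *= -1.0  # keep upper hemisphere
    # canonical order: descending z, then azimuth
    order = np.lexsort((np.arctan2(points[:, 1], points[:, 0]), -points[:, 2]))
    out = points[order]
    out.flags.writeable = False
    return out


def repulsion_directions(n: int) -> np.ndarray:
    """Return ``n`` repulsion-optimized unit vectors on the upper half-sphere.

    Deterministic (fixed start layout and iteration count); the returned
    array is read-only and cached.
    """
    if n < 1:
        raise ValueError("need at least one direction")
    return _repulsion_directions_cached(int(n))


#: The 15-direction set shipped with the default protocol
#: (output of ``repulsion_directions(15)``, frozen for reproducibility).
DIRECTIONS_15: np.ndarray = repulsion_directions(15)
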