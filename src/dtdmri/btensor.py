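"""Axisymmetric diffusion-encoding tensors (b-tensors).

A tensor-valued diffusion encoding is summarized by a symmetric
positive-semidefinite 3x3 matrix **b** whose trace equals the conventional
b-value.  For axisymmetric encodings the tensor is fully described by four
scalars: the magnitude ``b`` (s/m^2), the normalized anisotropy ``b_delta``
(-0.5 planar, 0 spherical, +1 linear), and the polar/azimuthal angles
(theta, phi) of the symmetry axis in the lab frame.

The axial and radial eigenvalues are

    b_par  = b (1 + 2 b_delta) / 3
    b_perp = b (1 -   b_delta) / 3

so that ``b = b_par + 2 b_perp`` and ``b_delta = (b_par - b_perp)/b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BTensor", "btensor_from_shape", "btensor_from_matrix", "unit_axis"]

#: admissible range of the normalized anisotropy
B_DELTA_MIN = -0.5
B_DELTA_MAX = 1.0


def unit_axis(theta: float, phi: float) -> np.ndarray:
    """Unit vector at polar angle ``theta`` (from lab z) and azimuth ``phi``."""
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


@dataclass(frozen=True)
class BTensor:
    """One axisymmetric diffusion-encoding tensor.

    Parameters
    ----------
    b :
        Trace magnitude (conventional b-value), s/m^2.
    b_delta :
        Normalized anisotropy in [-0.5, 1].
    theta_lab, phi_lab :
        Orientation of the symmetry axis, radians.
    """

    b: float
    b_delta: float
    theta_lab: float = 0.0
    phi_lab: float = 0.0
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ValueError(f"b must be nonnegative, got {self.b}")
        if not (B_DELTA_MIN <= self.b_delta <= B_DELTA_MAX):
            raise ValueError(
                f"b_delta must lie in [{B_DELTA_MIN}, {B_DELTA_MAX}], "
                f"got {self.b_delta}"
            )

    @property
    def b_par(self) -> float:
        """Axial eigenvalue b(1 + 2 b_delta)/3, s/m^2."""
        return self.b * (1.0 + 2.0 * self.b_delta) / 3.0

    @property
    def b_perp(self) -> float:
        """Radial eigenvalue b(1 - b_delta)/3, s/m^2."""
        return self.b * (1.0 - self.b_delta) / 3.0

    @property
    def axis(self) -> np.ndarray:
        """Unit symmetry axis in the lab frame."""
        return unit_axis(self.theta_lab, self.phi_lab)

    @property
    def matrix(self) -> np.ndarray:
        """Symmetric 3x3 tensor, s/m^2 (cached)."""
        if self._matrix is None:
            u = self.axis
            m = self.b_perp * np.eye(3) + (self.b_par - self.b_perp) * np.outer(u, u)
            object.__setattr__(self, "_matrix", m)
        return self._matrix

    def is_b0(self, threshold: float = 1e7) -> bool:
        """True when the magnitude is below ``threshold`` (default 1e7 s/m^2)."""
        return self.b < threshold


def btensor_from_shape(
    b: float, b_delta: float, theta_lab: float = 0.0, phi_lab: float = 0.0
) -> BTensor:
    """Construct a :class:`BTensor` from magnitude, shape and orientation."""
    return BTensor(float(b), float(b_delta), float(theta_lab), float(phi_lab))


def btensor_from_matrix(m: np.ndarray, axisym_rtol: float = 0.05) -> BTensor:
    """Recover (b, b_delta, theta, phi) from a symmetric 3x3 b-matrix.

    The two nearly-degenerate eigenvalues are averaged into the radial
    eigenvalue; the remaining one is axial.  If the degenerate pair differs
    by more than ``axisym_rtol * b`` the tensor is flagged non-axisymmetric.
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("b-matrix must be 3x3")
    if not np.allclose(m, m.T, atol=1e-12 * max(1.0, abs(m).max())):
        raise ValueError("b-matrix must be symmetric")
    vals, vecs = np.linalg.eigh(m)  # ascending
    b = float(vals.sum())
    if b <= 0:
        return BTensor(max(b, 0.0), 0.0)
    # pick the unique (axial) eigenvalue: the one farther from the other two
    if vals[1] - vals[0] <= vals[2] - vals[1]:
        b_par, b_perp = vals[2], 0.5 * (vals[0] + vals[1])
        pair_spread = vals[1] - vals[0]
        ax = vecs[:, 2]
    else:
        b_par, b_perp = vals[0], 0.5 * (vals[1] + vals[2])
        pair_spread = vals[2] - vals[1]
        ax = vecs[:, 0]
    if pair_spread > axisym_rtol * b:
        raise ValueError(
            f"b-matrix is not axisymmetric: degenerate eigenvalue pair "
            f"differs by {pair_spread:.3e} (> {axisym_rtol:.0%} of b={b:.3e})"
        )
    b_delta = float((b_par - b_perp) / b)
    b_delta = min(max(b_delta, B_DELTA_MIN), B_DELTA_MAX)
    if ax[2] < 0:  # axis is axial (u == -u); keep upper hemisphere
        ax = -ax
    theta = float(np.arccos(np.clip(ax[2], -1.0, 1.0)))
    phi = float(np.arctan2(ax[1], ax[0])) % (2.0 * np.pi)
    return BTensor(b, b_delta, theta, phi)
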