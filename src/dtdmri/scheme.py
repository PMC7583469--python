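"""Tensor-valued acquisition schemes: construction and text I/O.

An :class:`AcquisitionScheme` is an ordered list of b-tensors; the order
defines the layout of the per-voxel signal vector (the "acquisition point
index").  The default protocol samples 6 b-shells x 4 b-tensor shapes
(planar -0.5, spherical 0, prolate 0.5, linear 1) x 15 shared directions,
preceded by one b = 0 entry per shape, i.e. 364 acquisitions in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .btensor import BTensor, btensor_from_matrix, btensor_from_shape
from .directions import repulsion_directions

__all__ = [
    "AcquisitionScheme",
    "build_protocol",
    "read_scheme",
    "write_scheme",
    "PROTOCOL_B_VALUES",
    "PROTOCOL_B_DELTAS",
]

#: Default b-shells of the reference protocol, s/m^2.
PROTOCOL_B_VALUES: tuple[float, ...] = (
    0.042e9,
    0.173e9,
    0.388e9,
    1.080e9,
    2.116e9,
    3.499e9,
)

#: Default b-tensor shapes of the reference protocol.
PROTOCOL_B_DELTAS: tuple[float, ...] = (-0.5, 0.0, 0.5, 1.0)


@dataclass
class AcquisitionScheme:
    """Ordered list of b-tensors defining the signal-vector layout."""

    entries: list[BTensor]
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, arr in self.labels.items():
            if len(arr) != len(self.entries):
                raise ValueError(f"label '{key}' length != number of entries")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def b(self) -> np.ndarray:
        """Trace magnitudes, shape (n,), s/m^2."""
        return np.array([e.b for e in self.entries])

    @property
    def b_delta(self) -> np.ndarray:
        """Normalized anisotropies, shape (n,)."""
        return np.array([e.b_delta for e in self.entries])

    @property
    def axes(self) -> np.ndarray:
        """Unit symmetry axes, shape (n, 3)."""
        return np.array([e.axis for e in self.entries])

    def b0_mask(self, threshold: float = 1e7) -> np.ndarray:
        """Boolean mask of near-zero-b entries (default threshold 1e7 s/m^2)."""
        return self.b < threshold

    def require_b0(self, threshold: float = 1e7) -> None:
        """Raise unless at least one b0 entry exists (needed to anchor S0)."""
        if not self.b0_mask(threshold).any():
            raise ValueError(
                f"scheme has no entry with b < {threshold:g} s/m^2; "
                "at least one b0 acquisition is required"
            )

    def subset(self, indices: np.ndarray) -> "AcquisitionScheme":
        """Scheme restricted (with possible repetition) to ``indices``."""
        return AcquisitionScheme(
            entries=[self.entries[i] for i in indices],
            labels={k: v[indices] for k, v in self.labels.items()},
        )


def build_protocol(
    directions: int = 15,
    b_values: Sequence[float] = PROTOCOL_B_VALUES,
    shapes: Sequence[float] = PROTOCOL_B_DELTAS,
    n_b0: int = 4,
) -> AcquisitionScheme:
    """Build the default multi-shell, multi-shape protocol.

    The scheme starts with ``n_b0`` b = 0 entries (cycling through the shape
    list, one per shape by default) followed by, for each shape, each
    b-shell and each of the ``directions`` shared repulsion-optimized
    directions.  Defaults give 4 + 4 x 6 x 15 = 364 entries.

    Parameters
    ----------
    directions :
        Number of encoding directions shared across shells and shapes.
    b_values :
        Strictly positive, strictly increasing shell b-values, s/m^2.
    shapes :
        Normalized b-tensor anisotropies, each in [-0.5, 1].
    n_b0 :
        Number of leading b = 0 entries.
    """
    if directions < 1:
        raise ValueError("directions must be >= 1")
    b_values = list(b_values)
    if any(b <= 0 for b in b_values):
        raise ValueError("b_values must be strictly positive")
    if any(b2 <= b1 for b1, b2 in zip(b_values, b_values[1:])):
        raise ValueError("b_values must be strictly increasing")
    shapes = list(shapes)

    dirs = repulsion_directions(directions)
    thetas = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phis = np.arctan2(dirs[:, 1], dirs[:, 0]) % (2.0 * np.pi)

    entries: list[BTensor] = []
    shell_idx: list[int] = []
    shape_idx: list[int] = []
    dir_idx: list[int] = []
    for k in range(n_b0):
        entries.append(btensor_from_shape(0.0, shapes[k % len(shapes)]))
        shell_idx.append(-1)
        shape_idx.append(k % len(shapes))
        dir_idx.append(-1)
    for i_s, bd in enumerate(shapes):
        for i_b, b in enumerate(b_values):
            for i_d in range(directions):
                entries.append(btensor_from_shape(b, bd, thetas[i_d], phis[i_d]))
                shell_idx.append(i_b)
                shape_idx.append(i_s)
                dir_idx.append(i_d)
    return AcquisitionScheme(
        entries=entries,
        labels={
            "shell": np.array(shell_idx),
            "shape": np.array(shape_idx),
            "direction": np.array(dir_idx),
        },
    )


_DIALECTS = ("bdelta", "voigt")


def write_scheme(scheme: AcquisitionScheme, path, dialect: str = "bdelta") -> None:
    """Write a scheme as whitespace text.

    Two dialects: ``bdelta`` (columns b, b_delta, theta, phi) and ``voigt``
    (columns bxx, byy, bzz, bxy, bxz, byz).  A header declares dialect and
    units; values are written with 17 significant digits so a write/read
    round trip preserves every tensor element.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect '{dialect}', expected one of {_DIALECTS}")
    lines = [f"#dialect: {dialect}", "#units: s/m^2"]
    for e in scheme:
        if dialect == "bdelta":
            row = (e.b, e.b_delta, e.theta_lab, e.phi_lab)
        else:
            m = e.matrix
            row = (m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2])
        lines.append(" ".join(f"{v:.17e}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_scheme(path) -> AcquisitionScheme:
    """Read a scheme text file written by :func:`write_scheme`.

    Raises a :class:`ValueError` naming the offending line on unknown
    dialect headers, wrong column counts or non-finite values.
    """
    text = Path(path).read_text()
    dialect = None
    entries: list[BTensor] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("dialect:"):
                dialect = body.split(":", 1)[1].strip().lower()
                if dialect not in _DIALECTS:
                    raise ValueError(
                        f"{path}:{lineno}: unknown dialect '{dialect}' "
                        f"(expected one of {_DIALECTS})"
                    )
            continue
        if dialect is None:
            raise ValueError(
                f"{path}:{lineno}: data before '#dialect:' header"
            )
        fields = line.split()
        ncol = 4 if dialect == "bdelta" else 6
        if len(fields) != ncol:
            raise ValueError(
                f"{path}:{lineno}: expected {ncol} columns for dialect "
                f"'{dialect}', got {len(fields)}"
            )
        try:
            vals = [float(f) for f in fields]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparsable number") from exc
        if not all(np.isfinite(vals)):
            raise ValueError(f"{path}:{lineno}: non-finite value")
        if dialect == "bdelta":
            entries.append(btensor_from_shape(*vals))
        else:
            xx, yy, zz, xy, xz, yz = vals
            m = np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])
            entries.append(btensor_from_matrix(m))
    if dialect is None:
        raise ValueError(f"{path}: missing '#dialect:' header")
    return AcquisitionScheme(entries=entries)
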