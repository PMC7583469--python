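"""Variable-angle-spinning gradient waveforms for tensor-valued encoding.

A self-refocused gradient waveform g(t) generates the dephasing trajectory
q(t) = gamma * integral g dt and the encoding tensor B = integral q q^T dt.
The family implemented here places q on a cone at angle zeta around the lab
z-axis, with a smooth amplitude envelope f(t) = sin^2(pi t / T) and an
azimuth psi(t) that sweeps an integer number of turns at an angular velocity
proportional to 1/f(t)^2-weighted progress, i.e.

    q(t) = q0 f(t) [sin(zeta) cos(psi), sin(zeta) sin(psi), cos(zeta)],
    psi(t) = 2 pi n_turns * F(t),   F(t) = int_0^t f^2 / int_0^T f^2.

Reparametrizing the azimuthal integrals by F makes the transverse moments
average exactly, so the continuous-time b-tensor is axisymmetric with
normalized anisotropy b_delta = P2(cos zeta) = (3 cos^2 zeta - 1)/2, which
spans the full [-0.5, 1] range as zeta goes from 90 deg (planar) to 0
(linear).  This is one admissible realization of the variable-angle-spinning
idea; only the resulting b-tensor enters the analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .btensor import BTensor, btensor_from_matrix

__all__ = [
    "GAMMA_PROTON",
    "GradientWaveform",
    "generate_vas_waveform",
    "btensor_from_waveform",
    "write_waveform",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752218744e8


@dataclass
class GradientWaveform:
    """Sampled three-axis gradient waveform.

    Parameters
    ----------
    samples :
        Array (n, 3) of gradient amplitudes g(t), T/m, sampled at uniform
        interval ``dt`` starting at t = 0.
    dt :
        Sample interval, s.
    """

    samples: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        """Waveform duration, s."""
        return (len(self.samples) - 1) * self.dt

    @property
    def g_max(self) -> float:
        """Peak per-axis amplitude, T/m."""
        return float(np.abs(self.samples).max(initial=0.0))

    def q_trajectory(self, gamma: float = GAMMA_PROTON) -> np.ndarray:
        """Dephasing vector q(t) = gamma * cumulative integral of g, 1/m."""
        from scipy.integrate import cumulative_trapezoid

        return gamma * cumulative_trapezoid(
            self.samples, dx=self.dt, axis=0, initial=0.0
        )

    def is_refocused(self, rtol: float = 1e-6) -> bool:
        """True when the zeroth gradient moment vanishes per axis."""
        m0 = np.trapezoid(self.samples, dx=self.dt, axis=0)
        scale = self.g_max * self.duration
        return scale == 0.0 or bool(np.all(np.abs(m0) <= rtol * scale))


def _cone_q_trajectory(
    b_delta_target: float, duration: float, n_samples: int, n_turns: int
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude cone trajectory and times; |q| envelope sin^2(pi t/T)."""
    t = np.linspace(0.0, duration, n_samples)
    f = np.sin(np.pi * t / duration) ** 2
    cos2 = (2.0 * b_delta_target + 1.0) / 3.0  # P2(cos zeta) = target
    zeta = np.arccos(np.sqrt(np.clip(cos2, 0.0, 1.0)))
    # azimuthal progress proportional to the f^2-weighted time measure
    w = f**2
    prog = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]))])
    prog /= prog[-1]
    psi = 2.0 * np.pi * n_turns * prog
    q = np.column_stack(
        [
            f * np.sin(zeta) * np.cos(psi),
            f * np.sin(zeta) * np.sin(psi),
            f * np.cos(zeta),
        ]
    )
    return q, t


def generate_vas_waveform(
    b_delta_target: float,
    duration: float = 18e-3,
    g_max: float = 1.0,
    n_samples: int = 2000,
    b_target: float | None = None,
    n_turns: int = 4,
    gamma: float = GAMMA_PROTON,
) -> GradientWaveform:
    """Synthesize a self-refocused waveform with the requested b-tensor shape.

    The waveform is scaled so its peak per-axis gradient equals ``g_max``;
    if ``b_target`` (s/m^2) is given, it is instead scaled to reach that
    b-value, and an error is raised when doing so would exceed ``g_max``.

    Parameters
    ----------
    b_delta_target :
        Normalized b-tensor anisotropy in [-0.5, 1].
    duration :
        Waveform duration T_diff, s (default 18 ms).
    g_max :
        Peak per-axis gradient amplitude, T/m.
    n_samples :
        Number of time samples.
    """
    if not (-0.5 <= b_delta_target <= 1.0):
        raise ValueError("b_delta_target must lie in [-0.5, 1]")
    if duration <= 0:
        raise ValueError("duration must be positive")
    q_unit, t = _cone_q_trajectory(b_delta_target, duration, n_samples, n_turns)
    g_unit = np.gradient(q_unit, t, axis=0) / gamma
    peak = np.abs(g_unit).max()
    scale = g_max / peak
    if b_target is not None:
        # b scales with the square of the q (hence gradient) amplitude
        # actual q(t) = gamma * int g dt = scale * q_unit(t)
        b_at_gmax = _numerical_b(q_unit * scale, t)
        needed = np.sqrt(b_target / b_at_gmax)
        if needed > 1.0 + 1e-9:
            raise ValueError(
                f"b target {b_target:.3e} s/m^2 unreachable at "
                f"g_max={g_max} T/m, duration={duration} s: achievable "
                f"b = {b_at_gmax:.3e} s/m^2"
            )
        scale *= needed
    return GradientWaveform(samples=g_unit * scale, dt=t[1] - t[0])


def _numerical_b(q: np.ndarray, t: np.ndarray) -> float:
    return float(np.trapezoid((q**2).sum(axis=1), t))


def btensor_from_waveform(
    w: GradientWaveform, gamma: float = GAMMA_PROTON, axisym_rtol: float = 0.05
) -> BTensor:
    """b-tensor B = integral q(t) q(t)^T dt of a self-refocused waveform.

    Integration is trapezoidal; the matrix is symmetrized and converted to
    shape parameters by eigen-analysis.  Raises if the waveform is not
    refocused or if the eigenvalue structure is not axisymmetric within
    ``axisym_rtol`` of b.
    """
    if not w.is_refocused():
        raise ValueError("waveform is not self-refocused (nonzero zeroth moment)")
    q = w.q_trajectory(gamma)
    outer = q[:, :, None] * q[:, None, :]
    bmat = np.trapezoid(outer, dx=w.dt, axis=0)
    bmat = 0.5 * (bmat + bmat.T)
    return btensor_from_matrix(bmat, axisym_rtol=axisym_rtol)


def write_waveform(w: GradientWaveform, path) -> None:
    """Export as 3-column text (T/m) with the sample interval in the header."""
    header = f"#dt: {w.dt:.17e} s\n#columns: gx gy gz (T/m)\n"
    rows = "\n".join(" ".join(f"{v:.17e}" for v in row) for row in w.samples)
    from pathlib import Path

    Path(path).write_text(header + rows + "\n")
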