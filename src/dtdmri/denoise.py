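"""Random-matrix (Marchenko-Pastur PCA) denoising of acquisition series.

Each sliding in-plane window (default 3x3, clipped at image borders) yields
an M x N matrix X of M kernel voxels by N series points.  The eigenvalues of
X X^T / N separate into signal components and a noise bulk whose shape
follows the Marchenko-Pastur law; the bulk edge identifies the noise
variance and the number of significant components, and the window is
reconstructed from the signal components only.

Each voxel is covered by several overlapping windows; the denoised value is
the average of the reconstructions from all windows containing the voxel,
which suppresses residual noise well below what a single window achieves.
The per-voxel sigma estimate is likewise the average over covering windows,
while the retained-rank map reports the window centered on the voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DenoiseResult", "mppca_denoise"]


@dataclass
class DenoiseResult:
    """Denoised stack plus per-voxel noise SD and retained rank."""

    stack: np.ndarray  # same shape as input
    sigma_map: np.ndarray  # (nx, ny, nz)
    rank_map: np.ndarray  # (nx, ny, nz), int


def _mp_truncate(x: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Truncate the MP noise bulk of X (M x N); return (X_hat, sigma2, rank).

    Scans the number of retained signal components p upward and accepts the
    smallest p for which the remaining M - p eigenvalues fit inside a
    Marchenko-Pastur bulk: their spread must not exceed the MP bulk width
    4 sigma^2 sqrt((M - p)/N) with sigma^2 their mean.
    """
    m, n = x.shape
    c = (x @ x.T) / n
    vals, vecs = np.linalg.eigh(c)  # ascending
    p_sel, sigma2 = m - 1, float(max(vals[0], 0.0))
    tol = 1e-12 * max(float(vals[-1]), 0.0)  # absorbs numerically-zero spread
    for p in range(m):
        q = m - p
        s2 = float(vals[:q].mean())
        edge = 4.0 * s2 * np.sqrt(q / n)
        if vals[q - 1] - vals[0] <= edge + tol:
            p_sel, sigma2 = p, max(s2, 0.0)
            break
    if p_sel == 0:
        return np.zeros_like(x), sigma2, 0
    v = vecs[:, m - p_sel:]
    return v @ (v.T @ x), sigma2, p_sel


def mppca_denoise(stack: np.ndarray, kernel: int = 3) -> DenoiseResult:
    """Denoise a 4-D stack (x, y, z, series) slice by slice.

    Parameters
    ----------
    stack :
        Magnitude image stack, shape (nx, ny, nz, n_series).
    kernel :
        In-plane window side length (odd), default 3.

    Raises
    ------
    ValueError
        If the series axis is shorter than 2 or the kernel is even.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("stack must be 4-D (x, y, z, series)")
    nx, ny, nz, n_series = stack.shape
    if n_series < 2:
        raise ValueError("series axis must have length >= 2")
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError("kernel must be a positive odd integer")
    half = kernel // 2

    out = np.zeros_like(stack)
    hits = np.zeros((nx, ny, nz))
    sigma_sum = np.zeros((nx, ny, nz))
    sigma_hits = np.zeros((nx, ny, nz))
    rank_map = np.zeros((nx, ny, nz), dtype=int)

    for k in range(nz):
        for ci in range(nx):
            i0, i1 = max(ci - half, 0), min(ci + half + 1, nx)
            for cj in range(ny):
                j0, j1 = max(cj - half, 0), min(cj + half + 1, ny)
                window = stack[i0:i1, j0:j1, k, :]
                mwin = (i1 - i0) * (j1 - j0)
                x = window.reshape(mwin, n_series)
                x_hat, sigma2, rank = _mp_truncate(x)
                out[i0:i1, j0:j1, k, :] += x_hat.reshape(window.shape)
                hits[i0:i1, j0:j1, k] += 1.0
                sigma_sum[i0:i1, j0:j1, k] += np.sqrt(sigma2)
                sigma_hits[i0:i1, j0:j1, k] += 1.0
                rank_map[ci, cj, k] = rank

    out /= hits[..., None]
    sigma_map = sigma_sum / sigma_hits
    return DenoiseResult(stack=out, sigma_map=sigma_map, rank_map=rank_map)
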