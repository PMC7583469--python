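"""Nonparametric Monte Carlo inversion of the DTD signal equation.

Per voxel, the discrete DTD is found by a quasi-genetic
proliferation-mutation-extinction search: random candidate components are
drawn log-uniformly in diffusivity and uniformly in orientation, their
nonnegative weights are solved by NNLS against the multi-exponential design
matrix, the heaviest components survive, are mutated (diffusivities jittered
in log space, orientations by a small random rotation), merged with fresh
candidates, and the cycle repeats.  The final NNLS defines the weights and
S0.  Solution uncertainty is quantified by bootstrapping the acquisitions
with replacement (default 96 replicates) — each replicate refits a
resampled (signal, b-tensor) set, and the ensemble spread propagates into
every derived descriptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import nnls

from .dtd import DiscreteDTD, design_matrix
from .scheme import AcquisitionScheme

__all__ = [
    "InversionConfig",
    "DTDEnsemble",
    "fit_voxel_once",
    "fit_voxel",
    "fit_image",
]


@dataclass(frozen=True)
class InversionConfig:
    """Tunable parameters of the Monte Carlo inversion.

    Attributes
    ----------
    bounds_log10 :
        log10 interval for both D_par and D_perp in m^2/s; the default
        (-11.3, -8.3), i.e. 0.005-5 e-9 m^2/s, covers the descriptor bin
        space with margin.
    n_candidates :
        Components per NNLS solve in each iteration.
    n_survivors :
        Heaviest components carried (mutated) into the next iteration.
    n_iterations :
        Proliferation-mutation cycles.
    mutation_decades :
        Initial half-width of the uniform log10 diffusivity mutation.
    mutation_angle_deg :
        Initial half-width of the orientation jitter, degrees.
    mutation_decay :
        Geometric factor applied to both mutation scales after each
        iteration (annealing); 1.0 keeps them fixed.
    n_mutants :
        Mutated copies generated per survivor each iteration.
    n_bootstrap :
        Bootstrap replicates per voxel.
    max_components :
        Cap on the number of nonzero components kept in a returned DTD.
    """

    bounds_log10: tuple[float, float] = (-11.3, -8.3)
    n_candidates: int = 200
    n_survivors: int = 10
    n_iterations: int = 30
    mutation_decades: float = 0.2
    mutation_angle_deg: float = 45.0
    mutation_decay: float = 0.8
    n_mutants: int = 3
    n_bootstrap: int = 96
    seed: int = 0
    max_components: int = 50

    def __post_init__(self) -> None:
        lo, hi = self.bounds_log10
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("bounds_log10 must be a finite increasing pair")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if (self.n_mutants + 1) * self.n_survivors >= self.n_candidates:
            raise ValueError(
                "n_candidates must exceed (n_mutants + 1) * n_survivors"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "InversionConfig":
        d = json.loads(text)
        if "bounds_log10" in d:
            d["bounds_log10"] = tuple(d["bounds_log10"])
        return cls(**d)


@dataclass
class DTDEnsemble:
    """Bootstrap ensemble of DTD solutions for one voxel."""

    replicates: list[DiscreteDTD]
    rss: np.ndarray  # residual sum of squares per replicate

    def __post_init__(self) -> None:
        self.rss = np.asarray(self.rss, dtype=float)
        if len(self.rss) != len(self.replicates):
            raise ValueError("rss length != number of replicates")
        if (self.rss < 0).any():
            raise ValueError("RSS must be nonnegative")

    def __len__(self) -> int:
        return len(self.replicates)


@dataclass
class _SchemeArrays:
    """Precomputed per-acquisition arrays, shared across bootstrap fits."""

    b: np.ndarray
    b_delta: np.ndarray
    axes: np.ndarray

    @classmethod
    def from_scheme(cls, scheme: AcquisitionScheme) -> "_SchemeArrays":
        return cls(b=scheme.b, b_delta=scheme.b_delta, axes=scheme.axes)

    def take(self, idx: np.ndarray) -> "_SchemeArrays":
        return _SchemeArrays(self.b[idx], self.b_delta[idx], self.axes[idx])


def _draw_components(n: int, cfg: InversionConfig, rng: np.random.Generator):
    lo, hi = cfg.bounds_log10
    d_par = 10.0 ** rng.uniform(lo, hi, n)
    d_perp = 10.0 ** rng.uniform(lo, hi, n)
    cos_t = rng.uniform(-1.0, 1.0, n)  # uniform orientations on the sphere
    theta = np.arccos(cos_t)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    return d_par, d_perp, theta, phi


def _mutate(
    d_par, d_perp, theta, phi, cfg: InversionConfig,
    rng: np.random.Generator, anneal: float = 1.0,
):
    lo, hi = cfg.bounds_log10
    n = len(d_par)
    scale = cfg.mutation_decades * anneal
    eps = rng.uniform(-scale, scale, (2, n))
    d_par = 10.0 ** np.clip(np.log10(d_par) + eps[0], lo, hi)
    d_perp = 10.0 ** np.clip(np.log10(d_perp) + eps[1], lo, hi)

    # jitter each axis by a random small rotation about a random
    # perpendicular direction
    st = np.sin(theta)
    u = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    rand = rng.normal(size=(n, 3))
    perp = rand - (rand * u).sum(axis=1, keepdims=True) * u
    norm = np.linalg.norm(perp, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    perp /= norm
    half_ang = cfg.mutation_angle_deg * anneal
    ang = np.radians(rng.uniform(-half_ang, half_ang, n))
    u_new = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * perp
    u_new /= np.linalg.norm(u_new, axis=1, keepdims=True)
    theta = np.arccos(np.clip(u_new[:, 2], -1.0, 1.0))
    phi = np.arctan2(u_new[:, 1], u_new[:, 0]) % (2.0 * np.pi)
    return d_par, d_perp, theta, phi


def _design(arr: _SchemeArrays, d_par, d_perp, theta, phi) -> np.ndarray:
    d_iso = (d_par + 2.0 * d_perp) / 3.0
    with np.errstate(invalid="ignore", divide="ignore"):
        d_delta = np.where(d_iso > 0, (d_par - d_perp) / (3.0 * d_iso), 0.0)
    st = np.sin(theta)
    axes = np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])
    return design_matrix(arr.b, arr.b_delta, arr.axes, d_iso, d_delta, axes)


def _fit_once_arrays(
    signal: np.ndarray,
    arr: _SchemeArrays,
    cfg: InversionConfig,
    rng: np.random.Generator,
) -> tuple[DiscreteDTD, float]:
    if np.all(signal == 0):
        return DiscreteDTD.empty(), 0.0

    d_par, d_perp, theta, phi = _draw_components(cfg.n_candidates, cfg, rng)
    w = np.zeros(cfg.n_candidates)
    for it in range(cfg.n_iterations):
        a = _design(arr, d_par, d_perp, theta, phi)
        w, _ = nnls(a, signal)
        if it == cfg.n_iterations - 1:
            break
        # extinction: keep the heaviest survivors (stable order on ties)
        order = np.argsort(-w, kind="stable")
        keep = order[: cfg.n_survivors]
        keep = keep[w[keep] > 0]
        # elitism: carry the unmutated survivors along with their mutants so
        # the best components found so far are never lost
        parts = [(d_par[keep], d_perp[keep], theta[keep], phi[keep])]
        for _ in range(cfg.n_mutants):
            parts.append(
                _mutate(
                    d_par[keep], d_perp[keep], theta[keep], phi[keep],
                    cfg, rng, anneal=cfg.mutation_decay**it,
                )
            )
        n_fresh = cfg.n_candidates - (cfg.n_mutants + 1) * len(keep)
        parts.append(_draw_components(n_fresh, cfg, rng))
        d_par = np.concatenate([p[0] for p in parts])
        d_perp = np.concatenate([p[1] for p in parts])
        theta = np.concatenate([p[2] for p in parts])
        phi = np.concatenate([p[3] for p in parts])

    resid = a @ w - signal
    rss = float(resid @ resid)
    nz = np.flatnonzero(w > 0)
    nz = nz[np.argsort(-w[nz], kind="stable")][: cfg.max_components]
    dtd = DiscreteDTD(
        w=w[nz], d_par=d_par[nz], d_perp=d_perp[nz],
        theta=theta[nz], phi=phi[nz],
    )
    return dtd, rss


def fit_voxel_once(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    cfg: InversionConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[DiscreteDTD, float]:
    """Single Monte Carlo fit of one voxel's signal vector.

    Returns the fitted :class:`DiscreteDTD` (weights in signal units,
    S0 = sum of weights) and the residual sum of squares.  An all-zero
    signal returns an empty DTD with S0 = 0.
    """
    cfg = cfg or InversionConfig()
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(scheme):
        raise ValueError("signal length != scheme size")
    if (signal < 0).any():
        raise ValueError("signal must be nonnegative")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    return _fit_once_arrays(signal, _SchemeArrays.from_scheme(scheme), cfg, rng)


def fit_voxel(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    cfg: InversionConfig | None = None,
    base_seed: int | None = None,
) -> DTDEnsemble:
    """Bootstrap ensemble fit of one voxel.

    Replicate k (k = 1..n_bootstrap) resamples the acquisitions with
    replacement using a generator seeded by ``base_seed + k`` (``base_seed``
    defaults to ``cfg.seed``) and refits the resampled rows, so ensembles
    are exactly reproducible.
    """
    cfg = cfg or InversionConfig()
    signal = np.asarray(signal, dtype=float)
    if len(signal) != len(scheme):
        raise ValueError("signal length != scheme size")
    if (signal < 0).any():
        raise ValueError("signal must be nonnegative")
    base = cfg.seed if base_seed is None else int(base_seed)
    arr = _SchemeArrays.from_scheme(scheme)
    n = len(signal)
    replicates, rss = [], []
    for k in range(1, cfg.n_bootstrap + 1):
        rng = np.random.default_rng(base + k)
        idx = rng.integers(0, n, n)
        dtd, r = _fit_once_arrays(signal[idx], arr.take(idx), cfg, rng)
        replicates.append(dtd)
        rss.append(r)
    return DTDEnsemble(replicates=replicates, rss=np.array(rss))


def fit_image(
    stack: np.ndarray,
    scheme: AcquisitionScheme,
    cfg: InversionConfig | None = None,
    mask: np.ndarray | None = None,
    progress: bool = False,
) -> dict[tuple[int, int, int], DTDEnsemble]:
    """Independent bootstrap fits for every masked voxel of a 4-D stack.

    Per-voxel base seeds are derived deterministically from ``cfg.seed`` and
    the voxel's linear index, so a rerun with the same seed reproduces every
    ensemble bit for bit.
    """
    cfg = cfg or InversionConfig()
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 4:
        raise ValueError("stack must be 4-D (x, y, z, acquisition)")
    if stack.shape[-1] != len(scheme):
        raise ValueError(
            f"stack has {stack.shape[-1]} volumes but scheme has {len(scheme)}"
        )
    nx, ny, nz = stack.shape[:3]
    if mask is None:
        mask = np.ones((nx, ny, nz), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (nx, ny, nz):
        raise ValueError("mask shape must match the spatial grid")

    voxels = list(zip(*np.nonzero(mask)))
    iterator = voxels
    if progress:
        from tqdm import tqdm

        iterator = tqdm(voxels, desc="fit", unit="voxel")
    out: dict[tuple[int, int, int], DTDEnsemble] = {}
    for i, j, k in iterator:
        linear = int(np.ravel_multi_index((i, j, k), (nx, ny, nz)))
        base = int(
            np.random.SeedSequence([cfg.seed, linear]).generate_state(1)[0]
            % np.int64(2**31 - 1)
        )
        out[(int(i), int(j), int(k))] = fit_voxel(
            stack[i, j, k], scheme, cfg, base_seed=base
        )
    return out
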