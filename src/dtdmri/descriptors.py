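"""Scalar statistical descriptors of DTD ensembles and bin-resolved maps.

Each DTD is condensed to weight-normalized statistics over the
(D_iso, D_delta^2) distribution space: the total amplitude S0, means E[x],
variances Var[x] and the covariance Cov[D_iso, D_delta^2].  The space is
further divided into three rectangular bins that loosely capture the main
brain tissue classes by the visual appearance of their tensor glyphs:

    thin  (WM-like):  0.005 < D_iso / 1e-9 m^2/s < 2,  0.25 < D_delta^2 < 1
    thick (GM-like):  0.005 < D_iso / 1e-9 m^2/s < 2,  0    < D_delta^2 < 0.25
    big   (CSF-like): 2     < D_iso / 1e-9 m^2/s < 5,  0    < D_delta^2 < 1

Interval membership is half-open with the lower bound inclusive, so an
exactly isotropic component (D_delta^2 = 0) belongs to thick/big; the upper
bounds that coincide with the global limits of the space (D_delta^2 = 1,
D_iso = 5e-9) are closed so stick-like and maximally fast components are
not orphaned.  Per bin, the signal fraction, conditional moments and a
mean-orientation tensor (weighted dyadic of the component axes, which
respects the axial u = -u symmetry) are computed.

Bootstrap ensembles are condensed by taking the median of each scalar over
the replicates; the per-replicate sets are retained for histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dtd import DiscreteDTD
from .inversion import DTDEnsemble

__all__ = [
    "BinDefinition",
    "DEFAULT_BINS",
    "Moments",
    "BinStats",
    "DescriptorSet",
    "dtd_moments",
    "bin_resolve",
    "ensemble_medians",
    "quality_maps",
    "orientation_rgb",
]


@dataclass(frozen=True)
class BinDefinition:
    """Rectangular region of (D_iso, D_delta^2) space.

    Intervals are lower-inclusive; each upper bound is exclusive unless the
    corresponding ``closed_hi`` flag is set.
    """

    name: str
    d_iso: tuple[float, float]  # m^2/s
    d_delta2: tuple[float, float]  # dimensionless
    d_iso_closed_hi: bool = False
    d_delta2_closed_hi: bool = False

    def __post_init__(self) -> None:
        if self.d_iso[0] >= self.d_iso[1] or self.d_delta2[0] >= self.d_delta2[1]:
            raise ValueError(f"bin '{self.name}' has a degenerate interval")

    def contains(self, d_iso: np.ndarray, d_delta2: np.ndarray) -> np.ndarray:
        """Boolean membership for arrays of (D_iso, D_delta^2) pairs."""
        lo_i, hi_i = self.d_iso
        lo_d, hi_d = self.d_delta2
        in_iso = (d_iso >= lo_i) & (
            (d_iso <= hi_i) if self.d_iso_closed_hi else (d_iso < hi_i)
        )
        in_d2 = (d_delta2 >= lo_d) & (
            (d_delta2 <= hi_d) if self.d_delta2_closed_hi else (d_delta2 < hi_d)
        )
        return in_iso & in_d2


#: WM-like / GM-like / CSF-like default bins.
DEFAULT_BINS: tuple[BinDefinition, ...] = (
    BinDefinition("thin", (0.005e-9, 2e-9), (0.25, 1.0), d_delta2_closed_hi=True),
    BinDefinition("thick", (0.005e-9, 2e-9), (0.0, 0.25)),
    BinDefinition(
        "big", (2e-9, 5e-9), (0.0, 1.0),
        d_iso_closed_hi=True, d_delta2_closed_hi=True,
    ),
)


@dataclass
class Moments:
    """Weight-normalized moments of one DTD over (D_iso, D_delta^2)."""

    s0: float
    e_diso: float
    e_ddelta2: float
    var_diso: float
    var_ddelta2: float
    cov_diso_ddelta2: float
    defined: bool = True


def dtd_moments(dtd: DiscreteDTD) -> Moments:
    """Means, variances and covariance of D_iso and D_delta^2.

    E[x] = sum w_n x_n / sum w_n; Var and Cov are the corresponding central
    second moments.  An empty DTD (S0 = 0) yields NaN moments flagged
    ``defined=False``.
    """
    s0 = dtd.s0
    if dtd.n_components == 0 or s0 == 0.0:
        nan = float("nan")
        return Moments(0.0, nan, nan, nan, nan, nan, defined=False)
    p = dtd.w / s0
    x = dtd.d_iso
    y = dtd.d_delta**2
    ex, ey = float(p @ x), float(p @ y)
    return Moments(
        s0=s0,
        e_diso=ex,
        e_ddelta2=ey,
        var_diso=float(p @ x**2) - ex**2,
        var_ddelta2=float(p @ y**2) - ey**2,
        cov_diso_ddelta2=float(p @ (x * y)) - ex * ey,
    )


@dataclass
class BinStats:
    """Signal fraction and conditional statistics of one bin."""

    fraction: float
    e_diso: float
    e_ddelta2: float
    mean_axis: np.ndarray  # principal eigenvector of the weighted dyadic
    mean_tensor: np.ndarray  # weighted mean 3x3 diffusion tensor, m^2/s
    defined: bool = True


def bin_resolve(
    dtd: DiscreteDTD, bins: tuple[BinDefinition, ...] = DEFAULT_BINS
) -> dict[str, BinStats]:
    """Per-bin signal fractions, conditional moments and mean orientations.

    fraction = sum of in-bin weights / total weight; conditional moments are
    over in-bin components only.  The mean orientation is the principal
    eigenvector of sum_n w_n u_n u_n^T (the weighted dyadic), which is
    invariant under the axial symmetry u -> -u.  An empty bin reports
    fraction 0 with NaN moments flagged undefined.
    """
    out: dict[str, BinStats] = {}
    s0 = dtd.s0
    d_iso = dtd.d_iso
    d_delta2 = dtd.d_delta**2
    for b in bins:
        if dtd.n_components == 0 or s0 == 0.0:
            member = np.zeros(0, dtype=bool)
        else:
            member = b.contains(d_iso, d_delta2)
        wsum = float(dtd.w[member].sum()) if member.any() else 0.0
        if wsum == 0.0:
            nan = float("nan")
            out[b.name] = BinStats(
                0.0, nan, nan,
                np.full(3, nan), np.full((3, 3), nan), defined=False,
            )
            continue
        w = dtd.w[member]
        p = w / wsum
        axes = dtd.axes[member]
        dyad = (axes.T * w) @ axes
        evals, evecs = np.linalg.eigh(dyad)
        mean_axis = evecs[:, -1]
        if mean_axis[2] < 0:
            mean_axis = -mean_axis
        dpar, dperp = dtd.d_par[member], dtd.d_perp[member]
        tensors = (
            dperp[:, None, None] * np.eye(3)
            + (dpar - dperp)[:, None, None] * axes[:, :, None] * axes[:, None, :]
        )
        out[b.name] = BinStats(
            fraction=wsum / s0,
            e_diso=float(p @ d_iso[member]),
            e_ddelta2=float(p @ d_delta2[member]),
            mean_axis=mean_axis,
            mean_tensor=np.tensordot(p, tensors, axes=1),
        )
    return out


@dataclass
class DescriptorSet:
    """Median descriptors of one voxel's bootstrap ensemble.

    ``medians`` maps scalar names to the median over replicates;
    ``per_replicate`` keeps the full replicate-by-descriptor table for
    histogramming; ``bin_tensors`` holds the elementwise-median in-bin mean
    diffusion tensors.
    """

    medians: dict[str, float]
    per_replicate: pd.DataFrame
    bin_tensors: dict[str, np.ndarray] = field(default_factory=dict)


def ensemble_medians(
    ens: DTDEnsemble, bins: tuple[BinDefinition, ...] = DEFAULT_BINS
) -> DescriptorSet:
    """Condense a bootstrap ensemble into median scalar descriptors.

    Every scalar (S0, global moments, per-bin fractions and conditional
    means) is computed per replicate and then reduced by the median; NaNs
    from undefined moments are ignored in the median.
    """
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    rows = []
    tensors: dict[str, list[np.ndarray]] = {b.name: [] for b in bins}
    for dtd, rss in zip(ens.replicates, ens.rss):
        m = dtd_moments(dtd)
        row = {
            "s0": m.s0,
            "e_diso": m.e_diso,
            "e_ddelta2": m.e_ddelta2,
            "var_diso": m.var_diso,
            "var_ddelta2": m.var_ddelta2,
            "cov_diso_ddelta2": m.cov_diso_ddelta2,
            "rss": float(rss),
        }
        for name, bs in bin_resolve(dtd, bins).items():
            row[f"{name}_fraction"] = bs.fraction
            row[f"{name}_e_diso"] = bs.e_diso
            row[f"{name}_e_ddelta2"] = bs.e_ddelta2
            if bs.defined:
                tensors[name].append(bs.mean_tensor)
        rows.append(row)
    table = pd.DataFrame(rows)
    medians = {}
    for k in table:
        col = table[k].to_numpy(dtype=float)
        finite = np.isfinite(col)
        medians[k] = float(np.median(col[finite])) if finite.any() else float("nan")
    bin_tensors = {
        name: (np.median(np.stack(ts), axis=0) if ts else np.full((3, 3), np.nan))
        for name, ts in tensors.items()
    }
    return DescriptorSet(
        medians=medians, per_replicate=table, bin_tensors=bin_tensors
    )


def quality_maps(
    fits: dict[tuple[int, int, int], DTDEnsemble],
    stack: np.ndarray,
    scheme,
    shape: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit-quality and raw-signal-quality maps.

    Map 1: median S0 over replicates divided by sqrt(median RSS) — an
    SNR-like figure of the fit (inf where RSS is zero).  Map 2: over the
    spherical-encoding (b_delta = 0) entries of the highest b-shell, the
    per-voxel mean divided by SD of the measured signal; unavailable (all
    NaN, with a warning) when the scheme has no such entries.
    """
    import warnings

    if shape is None:
        shape = stack.shape[:3]
    map1 = np.full(shape, np.nan)
    for (i, j, k), ens in fits.items():
        s0_med = float(np.median([d.s0 for d in ens.replicates]))
        rss_med = float(np.median(ens.rss))
        map1[i, j, k] = np.inf if rss_med == 0.0 else s0_med / np.sqrt(rss_med)

    b, bd = scheme.b, scheme.b_delta
    sel = (bd == 0.0) & (b == b.max())
    map2 = np.full(shape, np.nan)
    if not sel.any():
        warnings.warn(
            "scheme has no spherical-encoding entries at the maximum b-value;"
            " high-b mean/SD map unavailable"
        )
        return map1, map2
    sub = stack[..., sel]
    sd = sub.std(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        map2 = np.where(sd > 0, sub.mean(axis=-1) / sd, np.inf)
    return map1, map2


def orientation_rgb(obj, mode: str = "axis") -> np.ndarray:
    """[R, G, B] color triple encoding an orientation.

    mode "axis": absolute components of the unit symmetry axis,
    [|x|, |y|, |z|].  mode "tensor": lab-frame diagonal of the mean
    diffusion tensor normalized by its largest element,
    [Dxx, Dyy, Dzz] / max(...).  Output clipped to [0, 1].
    """
    if mode == "axis":
        if isinstance(obj, BinStats):
            u = obj.mean_axis
        else:
            u = np.asarray(obj, dtype=float)
        n = np.linalg.norm(u)
        if n == 0 or not np.isfinite(n):
            raise ValueError("zero or undefined axis")
        return np.clip(np.abs(u / n), 0.0, 1.0)
    if mode == "tensor":
        if isinstance(obj, BinStats):
            t = obj.mean_tensor
        elif isinstance(obj, DiscreteDTD):
            from .dtd import tensor_from_component

            t = sum(
                c.w * tensor_from_component(c) for c in obj.components
            ) / obj.s0
        else:
            t = np.asarray(obj, dtype=float)
        diag = np.diag(t)
        m = diag.max()
        if not np.isfinite(m) or m <= 0:
            raise ValueError("zero or undefined tensor")
        return np.clip(diag / m, 0.0, 1.0)
    raise ValueError("mode must be 'axis' or 'tensor'")
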