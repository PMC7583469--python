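"""Synthetic ground-truth voxels and noisy phantom image stacks.

Preset voxel classes emulate the tissue environments the analysis is meant
to separate: CSF (fast isotropic, D_iso = 3.1e-9 m^2/s), cortical GM (slow,
mildly anisotropic: D_iso = 0.7e-9 m^2/s with squared normalized anisotropy
0.2), WM (slow, highly anisotropic), a CSF+GM partial-volume mixture, and
the three validation phantoms: "hex" (a reverse-hexagonal liquid crystal
with WM-like anisotropic diffusion), dodecane (slow isotropic, GM-like) and
water (fast isotropic, CSF-like).  Noise is Rician by default — magnitude of
a complex Gaussian perturbation — with the noise SD set by the target SNR of
the mean GM b0 signal (the in vivo acquisitions this emulates report
SNR = 26).
"""

from __future__ import annotations

from dataclasses import dataclass
import json
from pathlib import Path

import numpy as np

from .dtd import DiscreteDTD, predict_signal
from .scheme import AcquisitionScheme

__all__ = [
    "PRESET_LABELS",
    "VoxelGroundTruth",
    "SyntheticPhantom",
    "make_preset_voxel",
    "default_layout",
    "make_phantom_image",
    "estimate_snr",
]

PRESET_LABELS = ("CSF", "GM", "WM", "HEX", "DODECANE", "WATER", "MIX")


def _axisym(d_iso: float, d_delta: float) -> tuple[float, float]:
    """(D_par, D_perp) from isotropic diffusivity and normalized anisotropy."""
    return d_iso * (1.0 + 2.0 * d_delta), d_iso * (1.0 - d_delta)


# Preset single-voxel ground truths.  CSF and GM moments follow the in vivo
# values the pipeline should recover; the GM anisotropy sign is chosen
# prolate (+sqrt(0.2)).  WM/hex/dodecane/water diffusivities are plausible
# choices placed strictly inside their intended descriptor bins
# (thin / thick / big); they are configuration, not measured values.
_PRESETS: dict[str, list[tuple[float, float, float, float, float]]] = {
    # label -> list of (w, d_par, d_perp, theta, phi)
    "CSF": [(1.0, 3.1e-9, 3.1e-9, 0.0, 0.0)],
    "GM": [(1.0, *_axisym(0.7e-9, np.sqrt(0.2)), 0.0, 0.0)],
    "WM": [(1.0, 2.0e-9, 0.2e-9, np.pi / 2.0, 0.0)],
    "HEX": [(1.0, 1.5e-9, 0.1e-9, np.pi / 2.0, np.pi / 2.0)],
    "DODECANE": [(1.0, 0.8e-9, 0.8e-9, 0.0, 0.0)],
    "WATER": [(1.0, 2.3e-9, 2.3e-9, 0.0, 0.0)],
    "MIX": [
        (0.5, 3.1e-9, 3.1e-9, 0.0, 0.0),
        (0.5, *_axisym(0.7e-9, np.sqrt(0.2)), 0.0, 0.0),
    ],
}


@dataclass
class VoxelGroundTruth:
    """Known DTD of one synthetic voxel."""

    dtd: DiscreteDTD
    tissue_label: str


def make_preset_voxel(label: str) -> VoxelGroundTruth:
    """Ground-truth voxel for one of the preset tissue/phantom classes."""
    key = label.upper()
    if key not in _PRESETS:
        raise ValueError(f"unknown preset '{label}'; known: {PRESET_LABELS}")
    rows = _PRESETS[key]
    return VoxelGroundTruth(
        dtd=DiscreteDTD(
            w=np.array([r[0] for r in rows]),
            d_par=np.array([r[1] for r in rows]),
            d_perp=np.array([r[2] for r in rows]),
            theta=np.array([r[3] for r in rows]),
            phi=np.array([r[4] for r in rows]),
        ),
        tissue_label=key,
    )


def default_layout(n: int = 16) -> np.ndarray:
    """Concentric n x n label layout (object array; None = background).

    From the border inward: one-voxel noise-only background frame, WM and GM
    annuli, a one-voxel CSF+GM partial-volume (MIX) rim, and a CSF core.
    Ring widths scale with the grid; very small grids (< 10) drop the MIX
    rim.  The default 16 x 16 gives WM rings 1-2, GM 3-5, MIX 6 and a CSF
    core.
    """
    if n < 6:
        raise ValueError("layout needs n >= 6")
    layout = np.full((n, n), None, dtype=object)
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ring = np.minimum.reduce([ii, jj, n - 1 - ii, n - 1 - jj])
    rmax = (n - 1) // 2
    n_csf = max(1, rmax // 4)
    n_mix = 1 if rmax >= 4 else 0
    n_gm = -(-(rmax - 1 - n_csf - n_mix) // 2)  # ceil
    gm_start = 1 + (rmax - 1 - n_csf - n_mix - n_gm) + 1
    layout[ring >= 1] = "WM"
    layout[ring >= gm_start] = "GM"
    if n_mix:
        layout[ring >= gm_start + n_gm] = "MIX"
    layout[ring >= gm_start + n_gm + n_mix] = "CSF"
    return layout


@dataclass
class SyntheticPhantom:
    """Noisy 4-D stack plus everything needed to score a fit against truth."""

    stack: np.ndarray  # (nx, ny, 1, n_acq)
    layout: np.ndarray  # (nx, ny) object array of labels / None
    scheme: AcquisitionScheme
    sigma: float  # noise SD actually applied
    snr: float
    seed: int
    ground_truth: dict[str, VoxelGroundTruth]  # label -> truth

    def save(self, directory) -> None:
        """Write stack (NIfTI), scheme and ground truth (JSON) to a directory."""
        import nibabel as nib

        from .scheme import write_scheme

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nib.save(
            nib.Nifti1Image(self.stack.astype(np.float64), np.eye(4)),
            directory / "stack.nii",
        )
        write_scheme(self.scheme, directory / "scheme.txt")
        payload = {
            "snr": self.snr,
            "sigma": self.sigma,
            "seed": self.seed,
            "layout": [[c if c is not None else "" for c in row]
                       for row in self.layout],
            "ground_truth": {
                lab: json.loads(gt.dtd.to_json())
                for lab, gt in self.ground_truth.items()
            },
        }
        (directory / "ground_truth.json").write_text(json.dumps(payload, indent=1))


def make_phantom_image(
    layout: np.ndarray | int | None = None,
    scheme: AcquisitionScheme | None = None,
    snr: float = 26.0,
    seed: int = 0,
    noise: str = "rician",
) -> SyntheticPhantom:
    """Simulate a noisy 4-D acquisition stack over a 2-D voxel lattice.

    Per voxel the noiseless signal is the forward model of its preset DTD;
    background voxels carry zero signal (noise only).  The noise SD is
    sigma = (mean noiseless b0 signal of GM voxels) / snr, falling back to
    the mean over all tissue voxels when the layout contains no GM.  Noise
    is "rician" (|S + eps1 + i eps2|, the magnitude-image model) or
    "gaussian"; ``snr = inf`` returns the noiseless stack.

    Same (layout, scheme, snr, seed) always reproduces the identical stack.
    """
    if scheme is None:
        from .scheme import build_protocol

        scheme = build_protocol()
    if layout is None:
        layout = default_layout()
    elif isinstance(layout, int):
        layout = default_layout(layout)
    layout = np.asarray(layout, dtype=object)
    if snr <= 0:
        raise ValueError("snr must be positive (use np.inf for noiseless)")
    if noise not in ("rician", "gaussian"):
        raise ValueError("noise must be 'rician' or 'gaussian'")

    labels = sorted({c for c in layout.ravel() if c})
    truths = {lab: make_preset_voxel(lab) for lab in labels}
    signals = {lab: predict_signal(truths[lab].dtd, scheme) for lab in labels}

    nx, ny = layout.shape
    n_acq = len(scheme)
    clean = np.zeros((nx, ny, 1, n_acq))
    for i in range(nx):
        for j in range(ny):
            lab = layout[i, j]
            if lab:
                clean[i, j, 0] = signals[lab]

    b0 = scheme.b0_mask()
    if not b0.any():
        b0 = scheme.b == scheme.b.min()
    ref_labels = ["GM"] if "GM" in signals else labels
    if ref_labels:
        ref = float(np.mean([signals[lab][b0].mean() for lab in ref_labels]))
    else:
        ref = 1.0
    sigma = 0.0 if np.isinf(snr) else ref / snr

    if sigma == 0.0:
        noisy = clean.copy()
    else:
        rng = np.random.default_rng(seed)
        e1 = rng.normal(0.0, sigma, clean.shape)
        if noise == "rician":
            e2 = rng.normal(0.0, sigma, clean.shape)
            noisy = np.sqrt((clean + e1) ** 2 + e2**2)
        else:
            noisy = clean + e1
    return SyntheticPhantom(
        stack=noisy,
        layout=layout,
        scheme=scheme,
        sigma=sigma,
        snr=float(snr),
        seed=seed,
        ground_truth=truths,
    )


def estimate_snr(
    stack: np.ndarray,
    tissue_mask: np.ndarray,
    noise_mask: np.ndarray,
    b0_index: int = 0,
    correct_rician: bool = False,
) -> float:
    """SNR = mean tissue b0 signal / SD of the signal-free background.

    ``b0_index`` selects the b = 0 volume along the last axis.  With
    ``correct_rician`` the background SD (Rayleigh-distributed on magnitude
    images) is divided by sqrt(2 - pi/2) to recover the underlying complex
    Gaussian sigma.  Returns inf when the background SD is zero.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    noise_mask = np.asarray(noise_mask, dtype=bool)
    if not tissue_mask.any() or not noise_mask.any():
        raise ValueError("tissue and noise masks must be non-empty")
    if (tissue_mask & noise_mask).any():
        raise ValueError("tissue and noise masks must be disjoint")
    vol = stack[..., b0_index]
    mean_tissue = float(vol[tissue_mask].mean())
    sd_noise = float(vol[noise_mask].std(ddof=1))
    if correct_rician:
        sd_noise /= np.sqrt(2.0 - np.pi / 2.0)
    if sd_noise == 0.0:
        return float("inf")
    return mean_tissue / sd_noise
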