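"""End-to-end pipeline: simulate/load -> denoise -> fit -> descriptor maps.

A :class:`RunConfig` fully determines a run; it is serialized verbatim into
the output directory and a rerun with an equal config produces byte-identical
arrays.  Processing is single-slice 2-D (the data model allows a slice axis
of length 1).
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .denoise import mppca_denoise
from .descriptors import DEFAULT_BINS, BinDefinition, ensemble_medians, quality_maps
from .dtd import DiscreteDTD
from .inversion import DTDEnsemble, InversionConfig, fit_image
from .scheme import AcquisitionScheme, read_scheme
from .synthetic import make_phantom_image

__all__ = [
    "RunConfig",
    "run_pipeline",
    "compute_maps",
    "save_ensembles",
    "load_ensembles",
]

log = logging.getLogger("dtdmri")

#: Scalar maps written by the maps stage.
MAP_NAMES = (
    "s0", "e_diso", "e_ddelta2", "var_diso", "var_ddelta2", "cov_diso_ddelta2",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``stack_path`` (NIfTI, with ``scheme_path``) or ``simulate``
    (a dict of :func:`dtdmri.synthetic.make_phantom_image` keyword
    arguments) must be given.
    """

    out_dir: str
    scheme_path: str | None = None
    stack_path: str | None = None
    simulate: dict | None = None
    denoise: bool = True
    denoise_kernel: int = 3
    inversion: InversionConfig = field(default_factory=InversionConfig)
    bins: tuple[BinDefinition, ...] = DEFAULT_BINS
    seed: int = 0
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["bins"] = [dataclasses.asdict(b) for b in self.bins]
        return json.dumps(d, indent=1)


def save_ensembles(
    fits: dict[tuple[int, int, int], DTDEnsemble],
    path,
    cfg: InversionConfig | None = None,
) -> None:
    """Store per-voxel bootstrap ensembles as gzipped JSON."""
    payload = {
        "config": dataclasses.asdict(cfg) if cfg is not None else None,
        "voxels": {
            f"{i},{j},{k}": {
                "rss": ens.rss.tolist(),
                "replicates": [
                    {
                        "w": d.w.tolist(),
                        "d_par": d.d_par.tolist(),
                        "d_perp": d.d_perp.tolist(),
                        "theta": d.theta.tolist(),
                        "phi": d.phi.tolist(),
                    }
                    for d in ens.replicates
                ],
            }
            for (i, j, k), ens in fits.items()
        },
    }
    with gzip.open(path, "wt") as fh:
        json.dump(payload, fh)


def load_ensembles(path) -> dict[tuple[int, int, int], DTDEnsemble]:
    with gzip.open(path, "rt") as fh:
        payload = json.load(fh)
    out = {}
    for key, rec in payload["voxels"].items():
        ijk = tuple(int(v) for v in key.split(","))
        out[ijk] = DTDEnsemble(
            replicates=[DiscreteDTD(**r) for r in rec["replicates"]],
            rss=np.array(rec["rss"]),
        )
    return out


def compute_maps(
    fits: dict[tuple[int, int, int], DTDEnsemble],
    shape: tuple[int, int, int],
    bins: tuple[BinDefinition, ...] = DEFAULT_BINS,
) -> dict[str, np.ndarray]:
    """Median descriptor maps (NaN outside the fitted mask)."""
    names = list(MAP_NAMES) + [
        f"{b.name}_{suffix}"
        for b in bins
        for suffix in ("fraction", "e_diso", "e_ddelta2")
    ]
    maps = {name: np.full(shape, np.nan) for name in names}
    for (i, j, k), ens in fits.items():
        ds = ensemble_medians(ens, bins)
        for name in names:
            maps[name][i, j, k] = ds.medians.get(name, np.nan)
    return maps


def _save_nifti(arr: np.ndarray, path) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), np.eye(4)), path)


def _save_bin_rgb(maps: dict[str, np.ndarray], bins, path) -> None:
    """Additive [R, G, B] = (thin, thick, big) fraction composite as PNG."""
    import matplotlib.image

    names = [b.name for b in bins[:3]]
    rgb = np.stack(
        [np.nan_to_num(maps[f"{n}_fraction"][:, :, 0]) for n in names], axis=-1
    )
    matplotlib.image.imsave(path, np.clip(rgb, 0.0, 1.0))


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and write all artifacts into ``cfg.out_dir``.

    Writes: config copy, (simulated) raw stack + scheme + ground truth,
    denoised stack and noise maps, the ensemble store, one NIfTI per
    descriptor map, quality maps, a bin-fraction RGB composite and a log
    file.  Stage failures propagate with the stage name.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    (out / "config.json").write_text(cfg.to_json())

    manifest: dict[str, str | bool] = {"denoise": cfg.denoise}
    try:
        # ---- input stage --------------------------------------------------
        if cfg.simulate is not None:
            log.info("simulate: %s", cfg.simulate)
            sim_args = dict(cfg.simulate)
            sim_args.setdefault("seed", cfg.seed)
            phantom = make_phantom_image(**sim_args)
            scheme = phantom.scheme
            stack = phantom.stack
            phantom.save(out / "input")
            manifest["input"] = "simulated"
        elif cfg.stack_path and cfg.scheme_path:
            import nibabel as nib

            stack = np.asarray(nib.load(cfg.stack_path).dataobj, dtype=float)
            if stack.ndim == 3:
                stack = stack[:, :, None, :]
            scheme = read_scheme(cfg.scheme_path)
            manifest["input"] = str(cfg.stack_path)
        else:
            raise ValueError("config needs either 'simulate' or stack+scheme paths")
        scheme.require_b0()
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'input' failed: {exc}") from exc

    try:
        if cfg.denoise:
            log.info("denoise: kernel %d", cfg.denoise_kernel)
            res = mppca_denoise(stack, kernel=cfg.denoise_kernel)
            fit_input = res.stack
            _save_nifti(res.stack, out / "denoised.nii")
            _save_nifti(res.sigma_map, out / "sigma.nii")
            _save_nifti(res.rank_map, out / "rank.nii")
        else:
            log.info("denoise: disabled, fitting raw stack")
            fit_input = stack
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'denoise' failed: {exc}") from exc

    try:
        # negative values can appear after denoising magnitude data
        fit_input = np.clip(fit_input, 0.0, None)
        mask = fit_input[..., scheme.b0_mask()].mean(axis=-1) > 0
        log.info("fit: %d voxels, %d replicates", mask.sum(), cfg.inversion.n_bootstrap)
        fits = fit_image(fit_input, scheme, cfg.inversion, mask=mask)
        save_ensembles(fits, out / "ensembles.json.gz", cfg.inversion)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'fit' failed: {exc}") from exc

    try:
        log.info("maps")
        maps = compute_maps(fits, stack.shape[:3], cfg.bins)
        for name, arr in maps.items():
            _save_nifti(arr, out / f"map_{name}.nii")
        q1, q2 = quality_maps(fits, stack, scheme)
        _save_nifti(np.nan_to_num(q1, posinf=0.0), out / "quality_s0_sqrt_rss.nii")
        _save_nifti(np.nan_to_num(q2, posinf=0.0), out / "quality_highb_mean_sd.nii")
        _save_bin_rgb(maps, cfg.bins, out / "bin_fractions_rgb.png")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'maps' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("done: %s", out)
    log.removeHandler(handler)
    handler.close()
    return out
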