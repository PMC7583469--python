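"""Bootstrap Monte Carlo inversion of one noisy gray-matter voxel.

A GM-like ground truth (D_iso = 0.7e-9 m^2/s, D_delta^2 = 0.2) is imaged
with the 364-point protocol at SNR 26, inverted with 32 bootstrap
replicates (96 is the full production setting), and condensed to median
descriptors.
"""

import numpy as np

from dtdmri import (
    InversionConfig,
    build_protocol,
    dtd_moments,
    ensemble_medians,
    fit_voxel,
    make_preset_voxel,
    predict_signal,
)

scheme = build_protocol()
truth = make_preset_voxel("GM").dtd
clean = predict_signal(truth, scheme)

rng = np.random.default_rng(0)
sigma = truth.s0 / 26.0
noisy = np.sqrt((clean + rng.normal(0, sigma, clean.shape)) ** 2
                + rng.normal(0, sigma, clean.shape) ** 2)

ens = fit_voxel(noisy, scheme, InversionConfig(seed=0, n_bootstrap=32))
ds = ensemble_medians(ens)

gt = dtd_moments(truth)
print(f"{'':16s}{'truth':>10s}{'median fit':>12s}")
print(f"{'E[D_iso] (1e-9)':16s}{gt.e_diso * 1e9:10.3f}{ds.medians['e_diso'] * 1e9:12.3f}")
print(f"{'E[D_delta^2]':16s}{gt.e_ddelta2:10.3f}{ds.medians['e_ddelta2']:12.3f}")
print(f"{'thick fraction':16s}{1.0:10.3f}{ds.medians['thick_fraction']:12.3f}")
iqr = np.percentile(ds.per_replicate["e_diso"] * 1e9, [25, 75])
print(f"replicate IQR of E[D_iso]: [{iqr[0]:.3f}, {iqr[1]:.3f}]e-9 m^2/s")

# The median recovers the mean diffusivity to a few percent; the
# anisotropy carries the positive bias expected at this SNR, and the
# replicate spread quantifies the uncertainty of every descriptor.
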