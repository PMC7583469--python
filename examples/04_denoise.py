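"""Random-matrix denoising of a noisy phantom acquisition.

An 8x8 synthetic phantom at SNR 26 (Gaussian noise for a clean sigma
comparison; magnitude/Rician noise is the simulator default) is denoised
with the sliding 3x3 Marchenko-Pastur PCA kernel.
"""

import numpy as np

from dtdmri import build_protocol, make_phantom_image, mppca_denoise

scheme = build_protocol()
noisy = make_phantom_image(layout=8, scheme=scheme, snr=26.0, seed=0,
                           noise="gaussian")
clean = make_phantom_image(layout=8, scheme=scheme, snr=np.inf)

res = mppca_denoise(noisy.stack, kernel=3)
print(f"true noise SD:      {noisy.sigma:.4f}")
print(f"estimated (median): {np.median(res.sigma_map):.4f}")

tissue = np.array([[lab is not None for lab in row] for row in noisy.layout])
err_in = noisy.stack[tissue] - clean.stack[tissue]
err_out = res.stack[tissue] - clean.stack[tissue]
rmse_in = np.sqrt(np.mean(err_in**2))
rmse_out = np.sqrt(np.mean(err_out**2))
print(f"tissue-voxel RMSE to truth: {rmse_in:.4f} -> {rmse_out:.4f} "
      f"({rmse_in / rmse_out:.1f}x reduction)")
print(f"retained signal components per voxel: {np.unique(res.rank_map)}")

# The Marchenko-Pastur law identifies which covariance eigenvalues are
# pure noise; discarding them shrinks the error to the noiseless truth
# while estimating the noise SD from the data alone.
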