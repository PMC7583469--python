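"""Build the default tensor-valued acquisition protocol and inspect it.

The protocol interleaves four b-tensor shapes (planar b_delta = -0.5,
spherical 0, prolate 0.5, linear 1) over six b-shells and 15 shared
directions, plus one b = 0 image per shape: 364 acquisitions.
"""

import numpy as np

from dtdmri import build_protocol, write_scheme

scheme = build_protocol()
print(f"acquisitions: {len(scheme)}")
print(f"b-shells (1e9 s/m^2): {sorted(np.unique(scheme.b[scheme.b > 0]) / 1e9)}")
print(f"shapes (b_delta): {sorted(np.unique(scheme.b_delta))}")
print(f"b0 images: {int(scheme.b0_mask().sum())}")

write_scheme(scheme, "protocol.txt")
print("wrote protocol.txt (4-column b/b_delta/theta/phi dialect)")

# Each line of the printout is one axis of the measurement design: the
# shells set the diffusion weighting, the shapes separate isotropic from
# anisotropic microstructure, and the directions resolve orientation.
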