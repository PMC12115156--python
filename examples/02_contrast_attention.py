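"""Probe the fore-background contrast attention (FBC) block.

FBC predicts a foreground activation map, pools foreground- and
background-weighted channel descriptors, gates each through a sigmoid
affine map, and rescales every channel by the gate difference cf - cb.
Channels responding more to foreground than background are amplified.
"""

import numpy as np

from seanet import FBC
from seanet.tensor import Tensor

rng = np.random.default_rng(0)
fbc = FBC(channels=8, rng=rng).eval()

x = rng.normal(size=(1, 8, 16, 16)).astype(np.float32)
vf, vb, cf, cb = fbc.descriptors(Tensor(x))
out = fbc(Tensor(x))

print("input shape:", x.shape)
print("pooled foreground descriptor vf:", vf.data.shape)   # [B, 1, C]
print("channel gates cf (first 4):", np.round(cf.data[0, 0, :4], 3))
print("channel gates cb (first 4):", np.round(cb.data[0, 0, :4], 3))
print("gate difference cf-cb (first 4):",
      np.round((cf.data - cb.data)[0, 0, :4], 3))
print("output shape:", out.data.shape)
# The output is the input scaled per channel by (cf - cb): a positive
# difference marks a channel that separates targets from background.
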