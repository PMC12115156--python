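"""Receptive-field arithmetic of the detail-amplification block (MDAM).

Each branch stacks a k x 1 / 1 x k pair with a 3 x 3 convolution dilated
at rate k, plus the final 3 x 3 block: sequential conv extents telescope
to 1 + (k - 1) + 2k + 2 = 3k + 2 pixels per axis.
"""

from seanet import MDAMConfig, mdam_receptive_field

for kernels in [(3, 5, 7), (3, 7, 9), (5, 7, 9)]:
    cfg = MDAMConfig(in_channels=16, out_channels=16, branch_kernels=kernels)
    rf = mdam_receptive_field(cfg)
    print(f"branch kernels {kernels} -> receptive-field extents {rf}")
# With the default (3, 5, 7) triple the three branches see 11-, 17- and
# 23-pixel windows: fine texture and broad context are sampled at once,
# which is what makes faint targets separable from the background.
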