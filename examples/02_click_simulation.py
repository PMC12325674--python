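"""Simulate clinician clicks on a deliberately wrong segmentation.

The simulator diffs prediction and ground truth, weights each erroneous
voxel by its Euclidean distance to the border of the erroneous region,
normalizes the weights into a multinomial and samples a click: deep errors
attract clicks, fringe voxels rarely do.  False negatives yield positive
clicks (mark missing foreground), false positives negative clicks.
"""

import numpy as np

from clickseg import (
    BinaryMask,
    ClickSet,
    compute_error_field,
    encode_clicks,
    sample_click,
)

shape = (32, 32, 32)
gt = np.zeros(shape, np.uint8)
gt[10:20, 10:20, 10:20] = 1  # the true tumor
pred = np.zeros(shape, np.uint8)
pred[12:22, 12:22, 12:22] = 1  # shifted prediction: both FNs and FPs

field = compute_error_field(BinaryMask(pred), BinaryMask(gt))
print(f"erroneous voxels: {field.error_mask.sum()}  "
      f"(weights sum to {field.prob.sum():.6f})")

rng = np.random.default_rng(0)
clicks = ClickSet()
for t in range(1, 6):
    clicks.append(sample_click(field, t, rng))
for c in clicks:
    print(f"  t={c.t}: {c.sign:8s} click at {c.coord}")

channels = encode_clicks(clicks, shape, sigma_vox=2.0)
print(f"positive guidance channel peak: {channels.pos.data.max():.1f} "
      f"(Gaussian balls, truncated at 4 sigma, max-combined)")
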