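"""Generate a dual-modality phantom and inspect its normalized channels.

The phantom has one lobed tumor blob (elevated PET uptake, slightly denser
CT tissue) plus distractor hot spots outside the ground truth that mimic
metabolically active lymph nodes.  CT is windowed to [-200, 200] HU and
rescaled to [-1, 1]; PET is z-scored per scan.
"""

import numpy as np

from clickseg import PhantomSpec, generate_phantom

phantom = generate_phantom(PhantomSpec(seed=7))
pair = phantom.pair  # normalized CT + PET

gt = phantom.gt.data.astype(bool)
distr = phantom.distractors.data.astype(bool)
bg = ~gt & ~distr

print(f"volume shape            : {pair.shape}, spacing {pair.spacing_mm} mm")
print(f"tumor voxels            : {gt.sum()}  (distractor voxels: {distr.sum()})")
print(f"normalized CT range     : [{pair.ct.data.min():.3f}, {pair.ct.data.max():.3f}]")
print(f"normalized PET mean/sd  : {pair.pet.data.mean():.2e} / {pair.pet.data.std():.3f}")
print(f"PET z-score inside tumor: {pair.pet.data[gt].mean():+.2f}")
print(f"PET z-score background  : {pair.pet.data[bg].mean():+.2f}")
# The tumor sits several background SDs hot in PET - the signal the initial
# network learns - while distractors are comparably hot but are not tumor,
# which is exactly the false-positive mode negative clicks must fix.
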