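# clickseg

Two-stage interactive click refinement for 3D tumor segmentation in
dual-modality (PET-CT) volumes.

## What problem this solves

Automatic segmentation of the primary gross tumor volume (GTVt) in
head-and-neck PET-CT is good but not reliable enough to use unchecked, and
fully manual delineation is slow.  Click-based interactive segmentation
lets a clinician fix a model's mistakes with a handful of clicks — but
single-model interactive systems (DeepGrow, DeepEdit) trade non-interactive
accuracy against interactive responsiveness.  This package implements a
two-stage framework that removes the trade-off:

* a **2-channel initial network** f(CT, PET) produces the best
  non-interactive segmentation at t = 0;
* a **5-channel refinement network** g(CT, PET, p_{t-1}, C+, C-) consumes
  the previous sigmoid probability volume p_{t-1} (a *memory* carrying the
  segmentation state across interactions) plus positive/negative click
  guidance channels C± (Gaussian balls of peak 1 at the click coordinates),
  and re-segments after every click.

Clicks are simulated by an idealized clinician: erroneous voxels (prediction
XOR ground truth) are weighted by their Euclidean distance to the border of
the erroneous region, the weights normalized into a multinomial, and one
coordinate sampled per interaction — false negatives yield positive clicks,
false positives negative ones.

Training minimizes L = L_Dice + L_BCE (ε = 1e-5, BCE summed over voxels)
with AdamW and a cosine schedule; the refinement network is optimized at
*every* simulated interaction event, with its memory channel
gradient-detached between events and replaced by a neutral 0.5 volume with
probability p_drop = 0.2 (mask dropout).  Single-model baselines with a
click-free training fraction (0 % / 25 % / 50 %), ensembling with shared
click coordinates, and the interaction-aware evaluation protocol — DSC
(mean ± SD), HD95 (median/IQR of pooled 95th-percentile surface distances,
mm), number of clicks to threshold (NoC) and proportion of failures (PoF,
20-click budget) — are all included.

Everything runs on synthetic dual-modality phantoms (one hot tumor blob
plus distractor hot spots mimicking metabolically active lymph nodes), so
the whole pipeline is trainable and testable on one CPU with no data
download.  The conv-net stack is a small NumPy reverse-mode autodiff engine
(`clickseg.nn`) purpose-built for these 3D residual U-Nets.  See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from clickseg import (PhantomSpec, NetworkConfig, TrainingConfig,
                      generate_dataset, train_initial, train_refinement,
                      run_session)
from clickseg.session import TwoStageSegmenter

data = generate_dataset(30, PhantomSpec(), seed=123)
train, val, test = data[:20], data[20:26], data[26:]

cfg = TrainingConfig.desk_scale(seed=7)           # one-CPU schedule
init = train_initial(train, cfg, net_cfg=NetworkConfig.desk_scale(2),
                     val_dataset=val)
refine = train_refinement(train, init.net, cfg,
                          net_cfg=NetworkConfig.desk_scale(5),
                          val_dataset=val)

seg = TwoStageSegmenter(init.net, refine.net)
trace = run_session(test[0].pair, test[0].gt, seg, T=10,
                    rng=np.random.default_rng(0))
for t, rec in enumerate(trace.metrics):
    print(t, round(rec.dsc, 4), round(rec.hd95, 2))
```

This trains both stages on 20 phantoms (a few minutes on one CPU) and runs
a 10-click session on a held-out phantom.  Output of the script above
(`examples/03_interactive_session.py`):

```
t   clicks  DSC     HD95 (mm)
0   0       0.7613  15.56
1   1       0.8759  14.99
2   2       0.8805  14.87
...
10  10      0.8767  14.87
```

Read it as: the initial network alone reaches DSC ≈ 0.76 on this case; the
first click lands in the largest disagreement region and the refinement
network lifts the overlap to ≈ 0.88, with the probability-volume memory
carrying each refinement into the next step.  The HD95 plateau shows a
residual small false-positive spot this under-trained model never fully
removes — the larger experiment below, with four times the training data,
drives HD95 to ~1 mm.

The `examples/` directory holds one short narrative script per capability
(phantoms & normalization, click simulation, interactive sessions,
benchmarking); a thin CLI covers the same pipeline from the shell:

```bash
clickseg make-phantoms --out-dir data --n 100 --seed 1
clickseg train initial    --dataset-dir data --out initial.npz --seed 1
clickseg train refinement --dataset-dir data --out refine.npz \
         --initial-checkpoint initial.npz --seed 1
clickseg benchmark --dataset-dir data --initial-checkpoint initial.npz \
         --refinement-checkpoint refine.npz --out-dir bench
```

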