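# Methods

## The problem and the framework

Delineating the primary gross tumor volume (GTVt) in co-registered PET-CT of
the head and neck is slow and shows substantial interobserver variability.
Fully automatic segmentation helps but fails on hard cases, so a clinician
must be able to *correct* a model with minimal effort.  `clickseg`
implements a two-stage interactive click-refinement framework for this
setting:

* an **initial network** — a residual 3D U-Net with a 2-channel input
  (CT, PET) — produces the non-interactive segmentation at `t = 0`;
* a **refinement network** — the same architecture with a 5-channel input
  (CT, PET, previous probability volume, positive-click channel,
  negative-click channel) — consumes one simulated user click per
  interaction `t >= 1` and re-segments.

The sigmoid probability volume of the previous step is fed back as an input
channel: this *memory mechanism* chains the two models together and carries
the segmentation state across interaction events, so each click refines the
current state instead of restarting.  Training the two stages separately
removes the usual trade-off of single-model interactive systems (DeepGrow /
DeepEdit), where click-free training iterations buy non-interactive
accuracy at the cost of interactive responsiveness.  Those single-model
baselines are implemented too, as one 4-channel network (CT, PET, clicks;
no memory) trained with a configurable click-free fraction (0 % = DeepGrow;
25 % / 50 % = the DeepEdit variants).

## Click simulation

Clicks are simulated, never misplaced, by an idealized clinician model.
Given the current binarized prediction `S` and ground truth `G`:

1. the erroneous region is the voxelwise disagreement `S XOR G`;
2. each erroneous voxel is weighted by its exact Euclidean distance
   transform to the nearest non-erroneous voxel, computed jointly over the
   whole error mask (no per-component split), in voxel units (= mm on the
   isotropic 1 mm grid);
3. weights are normalized to sum to 1 and treated as a multinomial, from
   which one coordinate is sampled per interaction — deep interior errors
   attract clicks, fringe voxels rarely do;
4. the click is positive where the ground truth was missed (false
   negative) and negative where the prediction is spurious (false
   positive).

Clicks are rendered into two guidance volumes as Gaussian balls
`exp(-d^2 / 2 sigma^2)` of peak 1, truncated at radius `4 sigma`.  The ball
width is not prescribed by the interaction-encoding literature for this
grid; the default is `sigma = 2` voxels (configurable).  Overlapping balls
combine by voxelwise **maximum**, not sum, so repeated nearby clicks cannot
push the guidance channels out of `[0, 1]` and click order does not matter.

## Losses and training

All models minimize the uniform-weight composite loss
`L = L_Dice + L_BCE` with

```
L_Dice = 1 - (2 Σ p_i g_i + ε) / (Σ p_i + Σ g_i + ε),   ε = 1e-5
L_BCE  = -Σ [ g_i log p_i + (1 - g_i) log(1 - p_i) ]
```

The BCE is **summed** over voxels as written, so loss magnitudes scale with
volume size (a mean-reduction switch exists but defaults off).
Probabilities are clipped to `[1e-7, 1 - 1e-7]` before the logarithms;
outside the clipping band the loss is flat and its gradient zero.
Optimization is AdamW (decoupled weight decay 1e-5) with the learning rate
cosine-annealed to zero by the final epoch, mini-batch size 1.  Full-scale
defaults: lr 1e-4, at most 300 epochs, early stopping with patience 50.

**Refinement training** runs per interaction *event*: for each sample the
frozen initial network provides the starting volume, the number of
simulated clicks `K` is drawn uniformly (full-scale default 1..15), and
after *each* click the refinement network takes a forward pass, a loss
evaluation and an optimizer step before the next click is sampled — rather
than accumulating all events before one backward pass.  Consequences built
into the implementation:

* the memory channel between events is the refinement network's own latest
  output, **gradient-detached** (per-event stepping would contradict
  backpropagating through the event chain), exactly mirroring inference;
* with probability `p_drop` (default 0.2) the memory channel of an event is
  replaced by a neutral constant-0.5 volume (**mask dropout**, a
  whole-volume event).  This prevents the refinement network from leaning
  on the initial mask and keeps it responsive to clicks;
* the click-free Bernoulli draw of the baselines is taken independently
  per training iteration, not scheduled per epoch.

Checkpoint selection: highest validation DSC for the initial network;
highest mean validation DSC over interactions `0..T_val` for interactive
models, with a fixed simulator seed per epoch so epochs are comparable.

**Augmentation** (optional, on by default at full scale): random affine
transforms — rotations up to ±45° on all axes, scaling and shearing in
[-0.1, 0.1], translation within ±32 voxels — each with probability 0.5,
plus mirroring of each axis with probability 0.5; the identical transform
hits CT, PET and mask (nearest-neighbour for the mask).  CT additionally
gets gamma contrast in [0.5, 1.5], an intensity shift of 0.1, Gaussian
noise of SD 0.1 and Gaussian smoothing, each at probability 0.25; PET gets
no intensity augmentation.  Images are warped with linear interpolation and
edge-value padding; the mask with nearest-neighbour and zero padding.
Clicks are always simulated *after* augmentation, on the augmented
geometry, so guidance channels are never interpolated.

## Network stack

The networks are residual 3D U-Nets built on a small NumPy reverse-mode
autodiff engine written for this package (`clickseg.nn`): 3D convolution
(shift-and-add formulation, one channel-mixing product per kernel offset —
on a single CPU core severalfold faster than an im2col gather at these
channel widths), instance normalization, leaky ReLU, nearest-neighbour
upsampling and channel concatenation, with AdamW on top.  Gradients are
exact and are checked against central finite differences in the test
suite.

Architecture contract: channels `[16, 32, 64, 128, 256]`, strides
`[1, 2, 2, 2]`, two residual units, sigmoid output.  The first stride is 1
so the full-resolution stage sees click channels undiluted.  Block
internals are this package's own design: each encoder stage is one
residual unit (`residual_units` conv→instance-norm→LeakyReLU subunits, the
first conv carrying stride and channel change, a 1×1×1 strided conv on the
skip path when shapes differ); each decoder stage upsamples
nearest-neighbour, concatenates the encoder skip, mixes channels with a
1×1×1 projection and refines with a residual unit; the head is a 1×1×1
convolution to one logit channel.  Stages beyond the stride list (the
bottleneck) use stride 1.  Arrays carry no batch axis (batch size is 1
throughout).

A scaled-down configuration — channels `[8, 16, 32]`, strides `[1, 2, 2]`
— is the desk-scale default; with it the spatial extents must be divisible
by 4 (by 8 at full scale).

## Interaction loop and ensembling

`run_session` produces a per-interaction trace: `t = 0` is the initial
network's untouched output; each later step binarizes the previous output
(strict `p > 0.5`; a voxel at exactly 0.5 is background), builds the error
field against the ground truth, samples one click, appends it to the
retained click set, and re-runs the refinement network.  An empty error
field freezes the trace (needed for clicks-to-threshold bookkeeping)
rather than erroring.  Inference uses no test-time augmentation.

The ensemble variant averages member probabilities arithmetically at every
step and samples the single shared click from the *ensemble* prediction's
error field; all members receive the same click coordinates.  Each member
keeps its **own** previous output as its memory channel — shared click
coordinates are the only coupling between members; sharing the averaged
volume instead is a configurable alternative reading, but per-member
memory preserves each member's internal consistency and is the default.

## Evaluation

* **DSC** `2|G∩S| / (|G|+|S|)`; two empty masks score 1.
* **HD95**: boundary voxels are foreground voxels with a six-connected
  background neighbour (outside the volume counts as background, so
  edge-touching foreground is surface); both directed surface-distance
  sets are pooled, `D_v = D_{G→S} ∪ D_{S→G}`, and the 95th percentile
  taken with linear interpolation between order statistics.  Distances are
  in mm (isotropic 1 mm grid).  Exactly one empty mask yields `+inf` — such
  states can never pass an HD95 threshold — and is excluded from
  median/IQR aggregation with a logged count; two empty masks yield 0.
* **Aggregation**: DSC as mean ± SD; HD95 as median and IQR (Q3 − Q1,
  25th/75th percentiles, linear interpolation).
* **NoC**: first interaction index at which DSC ≥ threshold (0.75, 0.85)
  or HD95 < threshold (5.0, 2.5 mm), with a 20-click budget; a sample that
  never crosses is a failure.  Failed samples are *excluded* from the NoC
  mean by default (a switch includes them capped at 20) and reported
  through **PoF** = 100 · failures / total.
* **Benchmark protocol**: every sample is run three times with different
  simulator seeds; per-sample outcomes are averaged over repeats before
  dataset aggregation; tables report 0/1/5/10 clicks and the 0-10 average.

## Synthetic phantoms

Real head-and-neck PET-CT cannot ship with the package, so every stage is
exercised on generated phantoms mimicking that data's statistical
structure on a 48³ isotropic 1 mm grid (144³ available via the spec):

* **Ground truth**: one lobed blob — a random ellipsoid (radii 6-10 voxels)
  whose implicit surface is perturbed by a smooth random field.
* **CT**: smooth soft-tissue-scale anatomy (Gaussian-filtered noise around
  +40 HU), a +30 HU denser tumor, additive noise of SD 20 HU, clipped to
  [-200, 400] HU.
* **PET**: SUV-like scale — background ≈ 1 with smooth variation, tumor
  uptake elevated by 5.0 (a realistic primary-tumor-to-background
  contrast), **distractor hot spots** of node-like size (radius 2-4
  voxels) and tumor-like uptake placed strictly outside the ground truth,
  scanner-like Gaussian blur (σ = 1 voxel) and additive noise of SD 0.3.

The distractors are essential: they create the false-positive failure mode
of metabolically active lymph nodes, so negative clicks are genuinely
exercised.  Lowering `pet_tumor_contrast` makes the task strictly harder (a
tested difficulty knob).  Everything is determined by the seed; a dataset
regenerates bit-identically from its manifest.

What the phantoms do **not** model: real anatomy, multi-center intensity
variation, metal artifacts, PET/CT misregistration, or ambiguous tumor
boundaries.  Passing tests on phantoms therefore demonstrates that the
mechanism works — clicks move segmentations toward the reference — not
that clinical-grade accuracy would be reached on patient scans.

## Desk-scale problem sizes

The end-to-end experiment (`clickseg.experiments.desk_scale_experiment`,
also behind `scripts/acceptance.py`) uses sizes chosen as a deliberate
single-CPU working point: 80 training + 20 validation + 20 held-out test
phantoms at 48³; the scaled-down network; lr 1e-3 (the higher rate
compensates the short schedule) with 2 epochs for the initial network and
3 for the refinement network, which starts from scratch against an
already-trained first stage and sees only ~2 optimizer steps per sample
per epoch; no augmentation; 1..3 simulated interactions per refinement
training sample (click behaviour generalizes to longer sessions through
the memory chaining); 10-click test sessions repeated over 3 simulator
seeds; the 20-click NoC/PoF run on 8 test phantoms.  On one CPU core this
trains to an initial mean test DSC around 0.9 with a rising
DSC-vs-clicks curve.  On short schedules the cosine annealing reaches
zero one step *past* the final epoch, so every epoch trains at a nonzero
rate.

## Numerical choices and edge cases

* Binarization threshold strict (`p > 0.5`); ties are background.
* PET z-scoring is per scan over the whole volume (no body mask); a
  constant PET volume is an error, not a silent zero.
* BCE clipping delta 1e-7; Dice ε = 1e-5 (the both-empty Dice loss is
  exactly 0 by ε cancellation).
* Percentiles everywhere use linear interpolation.
* Master seeds derive per-component seeds via `numpy.random.SeedSequence`;
  all derived seeds are kept below 2^31.
* Checkpoints store parameters plus the architecture config and build
  seed; loading reproduces predictions bit-exactly.
* Voxel indexing is 0-based `(i, j, k)` over `(H, W, D)` everywhere,
  including click tables and NIfTI I/O; masks are written as unsigned
  8-bit.

## Known limitations

* The conv-net stack is CPU-bound NumPy; full-scale (144³, channels to
  256, 300 epochs) training is out of reach here — the architecture and
  recipes support it, but expect GPU-class runtimes elsewhere.
* The click simulator is idealized (never misplaces a click, favours large
  errors); real clinician behaviour differs, and click placement is known
  to matter.
* Single binary foreground class; no multi-class extension.
* No resampling/registration: inputs are assumed co-registered and
  isotropic (anisotropic NIfTI spacing only warns).
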