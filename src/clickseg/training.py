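"""Losses, regularization, augmentation and the three training recipes:
the non-interactive initial network, the click-refinement network with
per-interaction-event optimization, and single-model interactive baselines
with a click-free fraction (the DeepGrow / DeepEdit regimes).

The loss is the uniform-weight composite

    L = L_Dice + L_BCE,
    L_Dice = 1 - (2 sum_i p_i g_i + eps) / (sum_i p_i + sum_i g_i + eps),
    L_BCE  = -sum_i [ g_i log p_i + (1 - g_i) log(1 - p_i) ],

with eps = 1e-5 smoothing and the BCE summed (not averaged) over voxels, so
loss magnitudes scale with volume size.  Probabilities are clipped to
[1e-7, 1 - 1e-7] before the logarithms.

Refinement training optimizes at *every* interaction event: for each sample
the number of simulated clicks K is drawn uniformly from
``interactions_range`` (default 1..15), and after each simulated click a
forward pass, loss and optimizer step are taken before the next click is
sampled.  The memory channel carries the refinement network's own latest
output (gradient-detached) after the first event; with probability
``p_drop`` it is replaced by a neutral constant-0.5 volume (mask dropout),
which keeps the network responsive to clicks instead of leaning on the
initial mask.
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from scipy import ndimage

from . import nn
from .clicks import ClickSet, compute_error_field, encode_clicks, sample_click
from .clicks import DEFAULT_SIGMA_VOX
from .networks import (
    BASELINE_CHANNELS,
    INITIAL_CHANNELS,
    REFINEMENT_CHANNELS,
    NetworkConfig,
    SegmentationNetwork,
    build_network,
    input_stack,
)
from .session import SingleModelSegmenter, TwoStageSegmenter, run_session
from .volumes import (
    BinaryMask,
    ImageVolume,
    ProbabilityVolume,
    VolumePair,
    binarize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LossConfig",
    "AugmentConfig",
    "TrainingConfig",
    "TrainResult",
    "dice_loss",
    "bce_loss",
    "composite_loss",
    "apply_mask_dropout",
    "augment",
    "train_initial",
    "train_refinement",
    "train_baseline",
]

CLIP_DELTA = 1e-7


@dataclass(frozen=True)
class LossConfig:
    epsilon: float = 1e-5
    reduction: str = "sum"  # printed form of the BCE; "mean" available

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.reduction not in ("sum", "mean"):
            raise ValueError("reduction must be 'sum' or 'mean'")


def _as_array(x) -> np.ndarray:
    if isinstance(x, (ProbabilityVolume, BinaryMask, ImageVolume)):
        return x.data
    return np.asarray(x)


def dice_loss(p, g, eps: float = 1e-5) -> float:
    """Soft Dice loss in [0, 1]; the eps smoothing makes the both-empty case
    exactly 0 (eps/eps cancellation)."""
    pa = _as_array(p).astype(np.float64)
    ga = _as_array(g).astype(np.float64)
    if pa.shape != ga.shape:
        raise ValueError("shape mismatch")
    num = 2.0 * float((pa * ga).sum()) + eps
    den = float(pa.sum()) + float(ga.sum()) + eps
    return 1.0 - num / den


def bce_loss(p, g, reduction: str = "sum") -> float:
    """Binary cross-entropy summed over voxels (probabilities clipped to
    [1e-7, 1 - 1e-7] before the logarithms)."""
    pa = np.clip(_as_array(p).astype(np.float64), CLIP_DELTA, 1.0 - CLIP_DELTA)
    ga = _as_array(g).astype(np.float64)
    if pa.shape != ga.shape:
        raise ValueError("shape mismatch")
    ll = ga * np.log(pa) + (1.0 - ga) * np.log(1.0 - pa)
    total = -float(ll.sum())
    return total / pa.size if reduction == "mean" else total


def composite_loss(p, g, cfg: LossConfig = LossConfig()) -> float:
    """Uniform-weight sum of the Dice and BCE components."""
    return dice_loss(p, g, cfg.epsilon) + bce_loss(p, g, cfg.reduction)


def _composite_grad_wrt_logits(
    p: np.ndarray, g: np.ndarray, cfg: LossConfig
) -> np.ndarray:
    """d(L_Dice + L_BCE)/d(logit), with p = sigmoid(logit).

    BCE-through-sigmoid is (p - g) for the sum reduction wherever the
    probability is inside the clipping band (the loss is flat outside it);
    the Dice term is the quotient-rule derivative chained through
    p(1 - p).
    """
    p64 = p.astype(np.float64)
    g64 = g.astype(np.float64)
    live = (p64 > CLIP_DELTA) & (p64 < 1.0 - CLIP_DELTA)
    d_bce = np.where(live, p64 - g64, 0.0)
    if cfg.reduction == "mean":
        d_bce /= p64.size
    eps = cfg.epsilon
    num = 2.0 * float((p64 * g64).sum()) + eps
    den = float(p64.sum()) + float(g64.sum()) + eps
    d_dice_dp = -(2.0 * g64 * den - num) / den**2
    d_dice = d_dice_dp * p64 * (1.0 - p64)
    return (d_bce + d_dice).astype(np.float32)


def apply_mask_dropout(
    prev: ProbabilityVolume, p_drop: float, rng: np.random.Generator
) -> ProbabilityVolume:
    """With probability ``p_drop`` replace the whole memory volume with a
    neutral constant 0.5 (maximal uncertainty); otherwise pass it through
    unchanged.  A whole-volume event, not a per-voxel one."""
    if not 0.0 <= p_drop <= 1.0:
        raise ValueError("p_drop must be in [0, 1]")
    if p_drop > 0.0 and rng.random() < p_drop:
        return ProbabilityVolume(
            np.full(prev.shape, 0.5, dtype=np.float32), prev.spacing_mm
        )
    return prev


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Spatial + CT-intensity augmentation.

    Spatial: rotations up to +-45 degrees over all axes, scaling and
    shearing within [-0.1, 0.1], translation within +-``translate_vox``
    voxels, each applied with probability 0.5, plus mirroring over every
    axis with probability 0.5.  The identical transform hits CT, PET and
    the mask (nearest-neighbour for the mask, so it stays binary).

    Intensity (CT only): gamma contrast in [0.5, 1.5] at p=0.25, intensity
    shift of 0.1 at p=0.25, Gaussian noise SD 0.1 at p=0.25, Gaussian
    smoothing at p=0.25.  The PET channel receives no intensity
    augmentation.
    """

    rotate_deg: float = 45.0
    scale_range: float = 0.1
    shear_range: float = 0.1
    translate_vox: float = 32.0
    p_affine: float = 0.5
    p_mirror: float = 0.5
    gamma_range: tuple[float, float] = (0.5, 1.5)
    shift_offset: float = 0.1
    noise_sd: float = 0.1
    smooth_sigma: tuple[float, float] = (0.5, 1.5)
    p_intensity: float = 0.25


def _rotation_matrix(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment(
    pair: VolumePair,
    gt: BinaryMask,
    rng: np.random.Generator,
    cfg: AugmentConfig = AugmentConfig(),
) -> tuple[VolumePair, BinaryMask]:
    """Apply one random augmentation draw to a normalized sample.

    Clicks are always simulated *after* augmentation, on the augmented
    geometry, so guidance channels never need spatial interpolation.
    """
    shape = pair.shape
    M = np.eye(3)
    t = np.zeros(3)
    if rng.random() < cfg.p_affine:
        angles = np.deg2rad(rng.uniform(-cfg.rotate_deg, cfg.rotate_deg, 3))
        M = M @ _rotation_matrix(angles)
    if rng.random() < cfg.p_affine:
        M = M @ np.diag(1.0 + rng.uniform(-cfg.scale_range, cfg.scale_range, 3))
    if rng.random() < cfg.p_affine:
        S = np.eye(3)
        off = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
        for i, j in off:
            S[i, j] = rng.uniform(-cfg.shear_range, cfg.shear_range)
        M = M @ S
    if rng.random() < cfg.p_affine:
        t = rng.uniform(-cfg.translate_vox, cfg.translate_vox, 3)
    flips = rng.random(3) < cfg.p_mirror

    identity = np.allclose(M, np.eye(3)) and not t.any()
    center = (np.array(shape) - 1) / 2.0
    Minv = np.linalg.inv(M)
    offset = center - Minv @ (center + t)

    def warp(vol: np.ndarray, order: int) -> np.ndarray:
        if identity:
            out = vol.copy()
        else:
            mode = "nearest" if order > 0 else "constant"
            out = ndimage.affine_transform(
                vol.astype(np.float64), Minv, offset=offset, order=order,
                mode=mode, cval=0.0,
            )
        for ax in range(3):
            if flips[ax]:
                out = np.flip(out, axis=ax)
        return np.ascontiguousarray(out)

    ct = warp(pair.ct.data, order=1).astype(np.float32)
    pet = warp(pair.pet.data, order=1).astype(np.float32)
    gt_out = warp(gt.data, order=0)
    gt_out = (gt_out > 0.5).astype(np.uint8)

    # CT-only intensity augmentation (values nominally in [-1, 1])
    if rng.random() < cfg.p_intensity:
        gamma = rng.uniform(*cfg.gamma_range)
        ct01 = np.clip((ct + 1.0) / 2.0, 0.0, 1.0)
        ct = (np.power(ct01, gamma) * 2.0 - 1.0).astype(np.float32)
    if rng.random() < cfg.p_intensity:
        ct = ct + np.float32(rng.uniform(-cfg.shift_offset, cfg.shift_offset))
    if rng.random() < cfg.p_intensity:
        ct = ct + rng.normal(0.0, cfg.noise_sd, shape).astype(np.float32)
    if rng.random() < cfg.p_intensity:
        ct = ndimage.gaussian_filter(ct, rng.uniform(*cfg.smooth_sigma)).astype(
            np.float32
        )

    sp = pair.spacing_mm
    return (
        VolumePair(
            ImageVolume(ct, sp, pair.ct.modality),
            ImageVolume(pet, sp, pair.pet.modality),
        ),
        BinaryMask(gt_out, sp),
    )


# ---------------------------------------------------------------------------
# training configuration and loops


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings shared by all three recipes.

    Defaults follow the full-scale recipe: AdamW at lr 1e-4 cosine-annealed
    to zero, weight decay 1e-5, batch size 1, at most 300 epochs with early
    stopping at patience 50, mask dropout p_drop 0.2, and 1..15 simulated
    interactions per refinement training sample.  ``click_free_fraction``
    applies only to single-model baselines (0 is the DeepGrow regime; 0.25
    and 0.5 the DeepEdit variants); it is unused by two-stage training.
    """

    p_drop: float = 0.2
    interactions_range: tuple[int, int] = (1, 15)
    max_epochs: int = 300
    patience: int = 50
    lr: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 1
    click_free_fraction: float = 0.0
    seed: int = 0
    sigma_vox: float = DEFAULT_SIGMA_VOX
    loss: LossConfig = field(default_factory=LossConfig)
    use_augment: bool = True
    augment_cfg: AugmentConfig = field(default_factory=AugmentConfig)
    val_interactions: int = 10
    val_fraction: float = 0.2

    def __post_init__(self):
        if not 0.0 <= self.p_drop <= 1.0:
            raise ValueError("p_drop must be in [0, 1]")
        if not 0.0 <= self.click_free_fraction <= 1.0:
            raise ValueError("click_free_fraction must be in [0, 1]")
        if self.interactions_range[0] < 1:
            raise ValueError("interactions_range lower bound must be >= 1")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "TrainingConfig":
        """One-CPU settings for 48^3 phantoms: few epochs, a higher
        learning rate to compensate, no augmentation, and 1..3 simulated
        interactions per refinement sample (click effects generalize to
        longer sessions through the memory chaining)."""
        base = dict(
            max_epochs=2,
            patience=2,
            lr=1e-3,
            interactions_range=(1, 3),
            use_augment=False,
            val_interactions=5,
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class TrainResult:
    net: SegmentationNetwork
    history: list[dict]
    best_epoch: int
    best_val: float
    counters: dict


def _unwrap(sample) -> tuple[VolumePair, BinaryMask]:
    if hasattr(sample, "pair") and hasattr(sample, "gt"):
        return sample.pair, sample.gt
    pair, gt = sample
    return pair, gt


def _split(dataset: list, val_dataset: list | None, cfg: TrainingConfig):
    if val_dataset is not None:
        return list(dataset), list(val_dataset)
    if len(dataset) < 2:
        raise ValueError("need at least 2 samples for a train/validation split")
    n_val = max(1, round(cfg.val_fraction * len(dataset)))
    idx = np.random.default_rng(cfg.seed).permutation(len(dataset))
    val = [dataset[i] for i in idx[:n_val]]
    train = [dataset[i] for i in idx[n_val:]]
    return train, val


def _snapshot(net: SegmentationNetwork) -> dict[str, np.ndarray]:
    return {k: p.data.copy() for k, p in net.named_parameters().items()}


def _restore(net: SegmentationNetwork, snap: dict[str, np.ndarray]) -> None:
    for k, p in net.named_parameters().items():
        p.data = snap[k].copy()


def _train_step(
    net: SegmentationNetwork,
    opt: nn.AdamW,
    x: np.ndarray,
    g: np.ndarray,
    cfg: TrainingConfig,
) -> tuple[float, np.ndarray]:
    """One forward/backward/update; returns (loss value, probabilities)."""
    z = net.forward_logits(x)
    p = 1.0 / (1.0 + np.exp(-z.data[0].astype(np.float64)))
    loss = dice_loss(p, g, cfg.loss.epsilon) + bce_loss(p, g, cfg.loss.reduction)
    grad = _composite_grad_wrt_logits(p, g, cfg.loss)[None]
    opt.zero_grad()
    z.backward(grad.astype(z.data.dtype))
    opt.step()
    return float(loss), p.astype(np.float32)


def _maybe_augment(pair, gt, rng, cfg: TrainingConfig):
    if cfg.use_augment:
        return augment(pair, gt, rng, cfg.augment_cfg)
    return pair, gt


def train_initial(
    dataset: list,
    cfg: TrainingConfig,
    net_cfg: NetworkConfig | None = None,
    val_dataset: list | None = None,
) -> TrainResult:
    """Train the 2-channel non-interactive initial network.

    Best checkpoint by validation DSC; early stopping on ``cfg.patience``.
    """
    if not dataset:
        raise ValueError("empty dataset")
    train, val = _split(dataset, val_dataset, cfg)
    if net_cfg is None:
        net_cfg = NetworkConfig(in_channels=INITIAL_CHANNELS)
    if net_cfg.in_channels != INITIAL_CHANNELS:
        raise ValueError("initial network takes 2 input channels (CT, PET)")
    rng = np.random.default_rng(cfg.seed)
    net = build_network(net_cfg, seed=cfg.seed)
    opt = nn.AdamW(net.parameters(), cfg.lr, weight_decay=cfg.weight_decay)

    history, best, best_epoch, best_snap = [], -np.inf, -1, None
    from .evaluation import dsc as dsc_metric

    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(cfg.lr, epoch, cfg.max_epochs)
        order = rng.permutation(len(train))
        losses = []
        for i in order:
            pair, gt = _unwrap(train[i])
            pair, gt = _maybe_augment(pair, gt, rng, cfg)
            x = input_stack(pair, mode="initial")
            loss, _ = _train_step(net, opt, x, gt.data, cfg)
            losses.append(loss)
        val_dscs = []
        for s in val:
            pair, gt = _unwrap(s)
            p = ProbabilityVolume(net.predict(input_stack(pair, mode="initial")),
                                  pair.spacing_mm)
            val_dscs.append(dsc_metric(gt, binarize(p)))
        val_dsc = float(np.mean(val_dscs))
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dsc": val_dsc, "lr": opt.lr})
        logger.info("initial epoch %d loss %.4f val DSC %.4f", epoch,
                    history[-1]["train_loss"], val_dsc)
        if val_dsc > best:
            best, best_epoch, best_snap = val_dsc, epoch, _snapshot(net)
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_snap is not None:
        _restore(net, best_snap)
    return TrainResult(net, history, best_epoch, best, {})


def _session_mean_dsc(segmenter, val: list, T: int, seed: int) -> float:
    """Mean DSC over interactions 0..T across a validation set, with a fixed
    simulator seed so epochs are comparable."""
    means = []
    for s in val:
        pair, gt = _unwrap(s)
        trace = run_session(pair, gt, segmenter, T, np.random.default_rng(seed))
        means.append(np.mean([m.dsc for m in trace.metrics]))
    return float(np.mean(means))


def train_refinement(
    dataset: list,
    initial: SegmentationNetwork | TrainResult,
    cfg: TrainingConfig,
    net_cfg: NetworkConfig | None = None,
    val_dataset: list | None = None,
) -> TrainResult:
    """Train the 5-channel refinement network on top of a frozen initial
    network, taking an optimizer step at every simulated interaction event.

    Per sample: the frozen initial network provides the starting
    probability volume; K ~ U{interactions_range} clicks are simulated one
    at a time against the current binarized output, and after each click
    the refinement network is run and updated before the next click.  The
    memory channel is the refinement's own latest (detached) output after
    the first event, passed through mask dropout.  Checkpoint selection is
    by the highest mean validation DSC over interactions 0..``val_interactions``.
    """
    if isinstance(initial, TrainResult):
        initial = initial.net
    if initial is None:
        raise ValueError("a trained initial checkpoint is required")
    if initial.config.in_channels != INITIAL_CHANNELS:
        raise ValueError("the frozen first stage must be the 2-channel network")
    train, val = _split(dataset, val_dataset, cfg)
    if net_cfg is None:
        net_cfg = NetworkConfig(in_channels=REFINEMENT_CHANNELS)
    if net_cfg.in_channels != REFINEMENT_CHANNELS:
        raise ValueError("refinement network takes 5 input channels")
    rng = np.random.default_rng(cfg.seed)
    net = build_network(net_cfg, seed=cfg.seed + 1)
    opt = nn.AdamW(net.parameters(), cfg.lr, weight_decay=cfg.weight_decay)
    initial_frozen = _snapshot(initial)

    lo, hi = cfg.interactions_range
    n_events = 0
    n_dropped = 0
    val_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    history, best, best_epoch, best_snap = [], -np.inf, -1, None

    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(cfg.lr, epoch, cfg.max_epochs)
        order = rng.permutation(len(train))
        losses = []
        for i in order:
            pair, gt = _unwrap(train[i])
            pair, gt = _maybe_augment(pair, gt, rng, cfg)
            p0 = ProbabilityVolume(
                initial.predict(input_stack(pair, mode="initial")), pair.spacing_mm
            )
            memory = p0
            mask = binarize(memory)
            clicks = ClickSet()
            K = int(rng.integers(lo, hi + 1))
            logger.debug("refinement sample %d: K=%d interactions", i, K)
            for k in range(1, K + 1):
                field_ = compute_error_field(mask, gt)
                if field_.empty:
                    break
                clicks.append(sample_click(field_, k, rng))
                channels = encode_clicks(clicks, pair.shape, cfg.sigma_vox)
                mem_in = apply_mask_dropout(memory, cfg.p_drop, rng)
                n_events += 1
                if mem_in is not memory:
                    n_dropped += 1
                x = input_stack(pair, mem_in, channels, mode="refinement")
                loss, p = _train_step(net, opt, x, gt.data, cfg)
                losses.append(loss)
                memory = ProbabilityVolume(p, pair.spacing_mm)
                mask = binarize(memory)
        segmenter = TwoStageSegmenter(initial, net, cfg.sigma_vox)
        val_dsc = _session_mean_dsc(segmenter, val, cfg.val_interactions, val_seed)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_mean_dsc": val_dsc, "lr": opt.lr})
        logger.info("refinement epoch %d loss %.4f val mean DSC %.4f", epoch,
                    history[-1]["train_loss"], val_dsc)
        if val_dsc > best:
            best, best_epoch, best_snap = val_dsc, epoch, _snapshot(net)
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_snap is not None:
        _restore(net, best_snap)
    # the first stage must never have been touched
    for k, p in initial.named_parameters().items():
        if not np.array_equal(p.data, initial_frozen[k]):
            raise RuntimeError("initial network was modified during refinement training")
    counters = {"n_events": n_events, "n_dropped": n_dropped}
    return TrainResult(net, history, best_epoch, best, counters)


def train_baseline(
    dataset: list,
    cfg: TrainingConfig,
    net_cfg: NetworkConfig | None = None,
    val_dataset: list | None = None,
) -> TrainResult:
    """Train a single 4-channel interactive model with a click-free fraction.

    Each training iteration is click-free (all-zero guidance channels, one
    optimizer step) with probability ``cfg.click_free_fraction``, decided by
    an independent Bernoulli draw per iteration; otherwise K ~
    U{interactions_range} clicks are simulated against the model's own
    evolving output with a step per event.  No memory channel.
    ``click_free_fraction = 0`` reproduces the DeepGrow regime; 0.25 / 0.5
    are the DeepEdit variants; 1 degenerates to a non-interactive model.
    """
    train, val = _split(dataset, val_dataset, cfg)
    if net_cfg is None:
        net_cfg = NetworkConfig(in_channels=BASELINE_CHANNELS)
    if net_cfg.in_channels != BASELINE_CHANNELS:
        raise ValueError("baseline network takes 4 input channels")
    rng = np.random.default_rng(cfg.seed)
    net = build_network(net_cfg, seed=cfg.seed + 2)
    opt = nn.AdamW(net.parameters(), cfg.lr, weight_decay=cfg.weight_decay)
    lo, hi = cfg.interactions_range
    f = cfg.click_free_fraction

    n_iter = 0
    n_click_free = 0
    val_seed = int(np.random.SeedSequence(cfg.seed).generate_state(1)[0] % 2**31)
    history, best, best_epoch, best_snap = [], -np.inf, -1, None

    from .clicks import ClickChannels

    for epoch in range(cfg.max_epochs):
        opt.lr = nn.cosine_lr(cfg.lr, epoch, cfg.max_epochs)
        order = rng.permutation(len(train))
        losses = []
        for i in order:
            pair, gt = _unwrap(train[i])
            pair, gt = _maybe_augment(pair, gt, rng, cfg)
            n_iter += 1
            zero = ClickChannels.zeros(pair.shape)
            if f > 0.0 and rng.random() < f:
                n_click_free += 1
                x = input_stack(pair, channels=zero, mode="baseline")
                loss, _ = _train_step(net, opt, x, gt.data, cfg)
                losses.append(loss)
                continue
            p = ProbabilityVolume(
                net.predict(input_stack(pair, channels=zero, mode="baseline")),
                pair.spacing_mm,
            )
            mask = binarize(p)
            clicks = ClickSet()
            K = int(rng.integers(lo, hi + 1))
            for k in range(1, K + 1):
                field_ = compute_error_field(mask, gt)
                if field_.empty:
                    break
                clicks.append(sample_click(field_, k, rng))
                channels = encode_clicks(clicks, pair.shape, cfg.sigma_vox)
                x = input_stack(pair, channels=channels, mode="baseline")
                loss, pr = _train_step(net, opt, x, gt.data, cfg)
                losses.append(loss)
                mask = binarize(ProbabilityVolume(pr, pair.spacing_mm))
        segmenter = SingleModelSegmenter(net, cfg.sigma_vox)
        val_dsc = _session_mean_dsc(segmenter, val, cfg.val_interactions, val_seed)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_mean_dsc": val_dsc, "lr": opt.lr})
        logger.info("baseline(f=%.2f) epoch %d loss %.4f val mean DSC %.4f", f,
                    epoch, history[-1]["train_loss"], val_dsc)
        if val_dsc > best:
            best, best_epoch, best_snap = val_dsc, epoch, _snapshot(net)
        elif epoch - best_epoch >= cfg.patience:
            break
    if best_snap is not None:
        _restore(net, best_snap)
    counters = {"n_iterations": n_iter, "n_click_free": n_click_free}
    return TrainResult(net, history, best_epoch, best, counters)
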