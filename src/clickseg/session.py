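"""The interactive segmentation loop.

At ``t = 0`` a standard (non-interactive) model segments the CT/PET pair.
Each later interaction ``t >= 1`` compares the current binarized output to
the ground truth, samples one simulated click from the disagreement region,
and re-runs a refinement model on the 5-channel stack
``[CT, PET, previous probability, positive clicks, negative clicks]`` — the
previous probability volume acting as a memory that carries the
segmentation state across interaction events.  Single-model baselines
(DeepGrow / DeepEdit style) run the same loop without the memory channel,
using one 4-channel network for both stages.

An ensemble variant averages member probabilities at every step and samples
the single shared click per interaction from the ensemble prediction's
error field; every member receives the same click coordinates while keeping
its own previous output as its memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .clicks import ClickSet, compute_error_field, encode_clicks, sample_click
from .clicks import DEFAULT_SIGMA_VOX, ClickChannels
from .evaluation import MetricRecord, dsc, hd95
from .networks import SegmentationNetwork, input_stack
from .volumes import BinaryMask, ProbabilityVolume, VolumePair, binarize, write_nifti

__all__ = [
    "SessionTrace",
    "TwoStageSegmenter",
    "SingleModelSegmenter",
    "run_initial",
    "refine_step",
    "run_session",
    "ensemble_session",
]


@dataclass
class SessionTrace:
    """Per-interaction record of a session: probability volumes, thresholded
    masks, click-set snapshots and metrics, indexed by t = 0..T.

    Entry ``t`` has exactly ``t`` clicks; entry 0 is the initial model's
    untouched output.  ``converged_at`` is the first t whose error field was
    empty (the trace is frozen from there on), or ``None``.
    """

    probs: list[ProbabilityVolume] = field(default_factory=list)
    masks: list[BinaryMask] = field(default_factory=list)
    clicks: list[ClickSet] = field(default_factory=list)
    metrics: list[MetricRecord] = field(default_factory=list)
    converged_at: int | None = None

    def __len__(self) -> int:
        return len(self.probs)

    def export(self, out_dir: str | Path, write_probs: bool = False) -> None:
        """Write the click table, a per-t metrics table, and (optionally)
        per-t probability volumes as NIfTI."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if self.clicks:
            self.clicks[-1].to_table(out_dir / "clicks.tsv")
        lines = ["t\tdsc\thd95_mm"]
        for t, rec in enumerate(self.metrics):
            lines.append(f"{t}\t{rec.dsc:.6f}\t{rec.hd95:.6f}")
        (out_dir / "metrics.tsv").write_text("\n".join(lines) + "\n")
        if write_probs:
            for t, p in enumerate(self.probs):
                write_nifti(p, out_dir / f"prob_t{t:02d}.nii.gz")


class TwoStageSegmenter:
    """Initial network for t=0 plus a dedicated refinement network with a
    probability-volume memory channel for t>=1."""

    uses_memory = True

    def __init__(
        self,
        initial: SegmentationNetwork,
        refinement: SegmentationNetwork,
        sigma_vox: float = DEFAULT_SIGMA_VOX,
    ):
        self.initial = initial
        self.refinement = refinement
        self.sigma_vox = sigma_vox

    def predict_initial(self, pair: VolumePair) -> ProbabilityVolume:
        x = input_stack(pair, mode="initial")
        return ProbabilityVolume(self.initial.predict(x), pair.spacing_mm)

    def predict_refine(
        self, pair: VolumePair, prev: ProbabilityVolume, channels: ClickChannels
    ) -> ProbabilityVolume:
        x = input_stack(pair, prev, channels, mode="refinement")
        return ProbabilityVolume(self.refinement.predict(x), pair.spacing_mm)


class SingleModelSegmenter:
    """One 4-channel network for both stages: zero click channels at t=0,
    click channels but no memory at t>=1 (DeepGrow / DeepEdit regime)."""

    uses_memory = False

    def __init__(self, net: SegmentationNetwork, sigma_vox: float = DEFAULT_SIGMA_VOX):
        self.net = net
        self.sigma_vox = sigma_vox

    def predict_initial(self, pair: VolumePair) -> ProbabilityVolume:
        channels = ClickChannels.zeros(pair.shape)
        x = input_stack(pair, channels=channels, mode="baseline")
        return ProbabilityVolume(self.net.predict(x), pair.spacing_mm)

    def predict_refine(
        self, pair: VolumePair, prev: ProbabilityVolume, channels: ClickChannels
    ) -> ProbabilityVolume:
        x = input_stack(pair, channels=channels, mode="baseline")
        return ProbabilityVolume(self.net.predict(x), pair.spacing_mm)


def run_initial(pair: VolumePair, initial_model: SegmentationNetwork) -> ProbabilityVolume:
    """Plain non-interactive forward pass of the 2-channel initial network."""
    x = input_stack(pair, mode="initial")
    return ProbabilityVolume(initial_model.predict(x), pair.spacing_mm)


def refine_step(
    pair: VolumePair,
    prev: ProbabilityVolume,
    clicks: ClickSet,
    refine_model: SegmentationNetwork,
    sigma_vox: float = DEFAULT_SIGMA_VOX,
) -> ProbabilityVolume:
    """One refinement forward pass on [CT, PET, prev, pos, neg].

    ``prev`` must be the latest framework output (the memory mechanism); it
    is treated as data, with no gradient linkage at inference.
    """
    if len(clicks) == 0:
        raise ValueError("refine_step requires at least one click; use run_initial")
    channels = encode_clicks(clicks, pair.shape, sigma_vox)
    x = input_stack(pair, prev, channels, mode="refinement")
    return ProbabilityVolume(refine_model.predict(x), pair.spacing_mm)


def _record(trace: SessionTrace, prob: ProbabilityVolume, clicks: ClickSet, gt: BinaryMask) -> BinaryMask:
    mask = binarize(prob)
    trace.probs.append(prob)
    trace.masks.append(mask)
    trace.clicks.append(clicks.copy())
    trace.metrics.append(MetricRecord(dsc(gt, mask), hd95(gt, mask)))
    return mask


def run_session(
    pair: VolumePair,
    gt: BinaryMask,
    segmenter,
    T: int,
    rng: np.random.Generator,
) -> SessionTrace:
    """Run a full simulated interaction session of ``T`` clicks.

    t=0 is the initial prediction; for t = 1..T one click is sampled from
    the disagreement of the preceding binarized output with the ground
    truth, appended to the click set, and the refinement model re-run.  If
    the error field becomes empty the remaining steps copy the previous
    volume and the trace is flagged converged.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    if gt.shape != pair.shape:
        raise ValueError("ground truth shape mismatch")
    trace = SessionTrace()
    clicks = ClickSet()
    prob = segmenter.predict_initial(pair)
    mask = _record(trace, prob, clicks, gt)
    for t in range(1, T + 1):
        if trace.converged_at is None:
            field_ = compute_error_field(mask, gt)
            if field_.empty:
                trace.converged_at = t - 1
        if trace.converged_at is not None:
            _record(trace, prob, clicks, gt)
            continue
        clicks.append(sample_click(field_, t, rng))
        channels = encode_clicks(clicks, pair.shape, segmenter.sigma_vox)
        prob = segmenter.predict_refine(pair, prob, channels)
        mask = _record(trace, prob, clicks, gt)
    return trace


def ensemble_session(
    pair: VolumePair,
    gt: BinaryMask,
    members: list[TwoStageSegmenter],
    T: int,
    rng: np.random.Generator,
) -> SessionTrace:
    """Interactive session with an ensemble of two-stage members.

    The ensemble probability at every step is the arithmetic mean of the
    member probabilities; the single shared click per interaction is
    sampled from the *ensemble* prediction's error field, and every member
    receives the same click set while keeping its own previous output as
    its memory channel.
    """
    if not members:
        raise ValueError("ensemble requires at least one member")
    trace = SessionTrace()
    clicks = ClickSet()
    member_probs = [m.predict_initial(pair) for m in members]
    ens = ProbabilityVolume(
        np.mean([p.data for p in member_probs], axis=0).astype(np.float32),
        pair.spacing_mm,
    )
    mask = _record(trace, ens, clicks, gt)
    sigma = members[0].sigma_vox
    for t in range(1, T + 1):
        if trace.converged_at is None:
            field_ = compute_error_field(mask, gt)
            if field_.empty:
                trace.converged_at = t - 1
        if trace.converged_at is not None:
            _record(trace, ens, clicks, gt)
            continue
        clicks.append(sample_click(field_, t, rng))
        channels = encode_clicks(clicks, pair.shape, sigma)
        member_probs = [
            m.predict_refine(pair, p, channels)
            for m, p in zip(members, member_probs)
        ]
        ens = ProbabilityVolume(
            np.mean([p.data for p in member_probs], axis=0).astype(np.float32),
            pair.spacing_mm,
        )
        mask = _record(trace, ens, clicks, gt)
    return trace
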