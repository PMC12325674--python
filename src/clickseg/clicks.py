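"""Click representation, Gaussian-ball guidance encoding, and the simulated
clinician.

A click is a signed voxel coordinate: positive clicks mark missing foreground
(false negatives), negative clicks mark spurious foreground (false
positives).  Clicks are rendered into two guidance volumes as Gaussian balls
of peak 1 so the network sees a smooth, localized hint rather than a single
voxel.

The simulator plays an idealized clinician: it diffs the current prediction
against the ground truth, weights every erroneous voxel by its Euclidean
distance to the border of the erroneous region (deep interior errors are more
likely click targets than fringe voxels), normalizes the weights to a
multinomial distribution and samples one coordinate per interaction.  It
never misplaces a click.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, ProbabilityVolume

__all__ = [
    "Click",
    "ClickSet",
    "ClickChannels",
    "ErrorField",
    "encode_clicks",
    "compute_error_field",
    "sample_click",
]

POSITIVE = "positive"
NEGATIVE = "negative"

#: Default Gaussian-ball width (voxels); balls are truncated at radius 4*sigma.
DEFAULT_SIGMA_VOX = 2.0


@dataclass(frozen=True)
class Click:
    """A single signed user click at voxel ``coord`` on interaction ``t >= 1``."""

    coord: tuple[int, int, int]
    sign: str
    t: int

    def __post_init__(self) -> None:
        if self.sign not in (POSITIVE, NEGATIVE):
            raise ValueError(f"sign must be '{POSITIVE}' or '{NEGATIVE}', got {self.sign!r}")
        if self.t < 1:
            raise ValueError(f"interaction index t must be >= 1, got {self.t}")
        object.__setattr__(self, "coord", tuple(int(c) for c in self.coord))


class ClickSet:
    """Ordered, append-only list of clicks; all clicks are retained across
    interaction events and the interaction index t must strictly increase."""

    def __init__(self, clicks: list[Click] | None = None):
        self._clicks: list[Click] = []
        for c in clicks or []:
            self.append(c)

    def append(self, click: Click) -> None:
        if self._clicks and click.t <= self._clicks[-1].t:
            raise ValueError(
                f"click t={click.t} does not increase on previous t={self._clicks[-1].t}"
            )
        self._clicks.append(click)

    def __len__(self) -> int:
        return len(self._clicks)

    def __iter__(self):
        return iter(self._clicks)

    def __getitem__(self, idx: int) -> Click:
        return self._clicks[idx]

    def copy(self) -> "ClickSet":
        return ClickSet(list(self._clicks))

    def to_table(self, path: str | Path) -> None:
        """Serialize one click per line as ``t<TAB>i<TAB>j<TAB>k<TAB>sign``."""
        lines = ["t\ti\tj\tk\tsign"]
        for c in self._clicks:
            lines.append(f"{c.t}\t{c.coord[0]}\t{c.coord[1]}\t{c.coord[2]}\t{c.sign}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "ClickSet":
        cs = cls()
        for line in Path(path).read_text().splitlines()[1:]:
            if not line.strip():
                continue
            t, i, j, k, sign = line.split("\t")
            cs.append(Click((int(i), int(j), int(k)), sign, int(t)))
        return cs


@dataclass
class ClickChannels:
    """The two guidance volumes (positive / negative clicks)."""

    pos: ProbabilityVolume
    neg: ProbabilityVolume

    def __post_init__(self) -> None:
        if self.pos.shape != self.neg.shape:
            raise ValueError("positive/negative channels must share a shape")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pos.shape

    @classmethod
    def zeros(cls, shape: tuple[int, int, int]) -> "ClickChannels":
        z = np.zeros(shape, dtype=np.float32)
        return cls(ProbabilityVolume(z.copy()), ProbabilityVolume(z.copy()))


def _gaussian_ball(sigma: float) -> np.ndarray:
    """A cubic patch holding exp(-d^2 / (2 sigma^2)), zeroed beyond radius 4*sigma."""
    r = int(np.ceil(4.0 * sigma))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    ball = np.exp(-d2 / (2.0 * sigma**2))
    ball[np.sqrt(d2) > 4.0 * sigma] = 0.0
    return ball.astype(np.float32)


def encode_clicks(
    clicks: ClickSet,
    shape: tuple[int, int, int],
    sigma_vox: float = DEFAULT_SIGMA_VOX,
) -> ClickChannels:
    """Render a click set into the two Gaussian-ball guidance channels.

    Each click contributes a ball of peak 1 centred on its coordinate to the
    channel matching its sign; overlapping balls combine by voxelwise
    maximum, so values stay in [0, 1] no matter how many clicks pile up.
    An empty click set yields two all-zero channels.
    """
    if sigma_vox <= 0:
        raise ValueError(f"sigma_vox must be positive, got {sigma_vox}")
    pos = np.zeros(shape, dtype=np.float32)
    neg = np.zeros(shape, dtype=np.float32)
    ball = _gaussian_ball(sigma_vox)
    r = ball.shape[0] // 2
    for c in clicks:
        i, j, k = c.coord
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
            raise ValueError(f"click {c.coord} outside volume of shape {shape}")
        target = pos if c.sign == POSITIVE else neg
        lo = [max(0, x - r) for x in (i, j, k)]
        hi = [min(n, x + r + 1) for x, n in zip((i, j, k), shape)]
        blo = [l - (x - r) for l, x in zip(lo, (i, j, k))]
        bhi = [b + (h - l) for b, l, h in zip(blo, lo, hi)]
        patch = ball[blo[0] : bhi[0], blo[1] : bhi[1], blo[2] : bhi[2]]
        view = target[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        np.maximum(view, patch, out=view)
    np.clip(pos, 0.0, 1.0, out=pos)
    np.clip(neg, 0.0, 1.0, out=neg)
    return ClickChannels(ProbabilityVolume(pos), ProbabilityVolume(neg))


FN = 1
FP = -1


@dataclass
class ErrorField:
    """Disagreement between a prediction and the ground truth, with the
    distance-weighted multinomial the simulator samples clicks from.

    ``error_mask`` is the voxelwise XOR of prediction and ground truth;
    ``sign_map`` tags each error voxel FN (+1, missing foreground) or FP
    (-1, spurious foreground); ``prob`` is zero off the error mask and sums
    to 1 over it (Euclidean distance to the border of the erroneous region,
    normalized by the sum of all distances).
    """

    error_mask: np.ndarray  # bool
    sign_map: np.ndarray  # int8: +1 FN, -1 FP, 0 elsewhere
    prob: np.ndarray  # float64, sums to 1 over error voxels
    empty: bool

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.error_mask.shape


def compute_error_field(pred: BinaryMask, gt: BinaryMask) -> ErrorField:
    """Build the click-sampling distribution from a prediction/ground-truth pair.

    Every erroneous voxel gets weight equal to its exact Euclidean distance
    transform to the nearest non-erroneous voxel (in voxel units; equal to mm
    on the default isotropic 1 mm grid), computed jointly over the whole
    error mask; weights are normalized to sum to 1.  If prediction and
    ground truth agree everywhere the field is flagged ``empty`` and must
    not be sampled from.
    """
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    p = pred.data.astype(bool)
    g = gt.data.astype(bool)
    err = p ^ g
    sign = np.zeros(err.shape, dtype=np.int8)
    sign[g & ~p] = FN
    sign[p & ~g] = FP
    if not err.any():
        return ErrorField(err, sign, np.zeros(err.shape, dtype=np.float64), True)
    dist = ndimage.distance_transform_edt(err)
    prob = np.asarray(dist, dtype=np.float64)
    prob /= prob.sum()
    return ErrorField(err, sign, prob, False)


def sample_click(field: ErrorField, t: int, rng: np.random.Generator) -> Click:
    """Draw one interaction coordinate from the error field's multinomial.

    The click is positive when the sampled voxel is a false negative (the
    user marks missing foreground) and negative when it is a false positive.
    Bit-exact reproducible for a fixed generator state.
    """
    if field.empty:
        raise ValueError("cannot sample a click from an empty error field")
    flat_idx = np.flatnonzero(field.error_mask)
    weights = field.prob.ravel()[flat_idx]
    pick = rng.choice(flat_idx.size, p=weights)
    coord = np.unravel_index(flat_idx[pick], field.shape)
    sign = POSITIVE if field.sign_map[coord] == FN else NEGATIVE
    return Click(tuple(int(c) for c in coord), sign, t)
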