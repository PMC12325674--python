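"""Segmentation network construction: the 2-channel initial network, the
5-channel refinement network, and the 4-channel single-model baseline, all
one residual U-Net family differing only in input width.

Input channel order is fixed and part of the contract:

* initial:    ``[CT, PET]``
* baseline:   ``[CT, PET, pos clicks, neg clicks]``
* refinement: ``[CT, PET, previous probability, pos clicks, neg clicks]``

The default configuration is channels ``[16, 32, 64, 128, 256]``, strides
``[1, 2, 2, 2]`` and two residual units; the first stride is 1 so the
full-resolution stage sees the click channels undiluted.  A scaled-down
configuration (channels ``[8, 16, 32]``, strides ``[1, 2, 2]``) is provided
for desk-scale experiments on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .clicks import ClickChannels
from .volumes import ProbabilityVolume, VolumePair

__all__ = [
    "NetworkConfig",
    "SegmentationNetwork",
    "build_network",
    "input_stack",
    "save_checkpoint",
    "load_checkpoint",
]

INITIAL_CHANNELS = 2
BASELINE_CHANNELS = 4
REFINEMENT_CHANNELS = 5


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``strides[i]`` is the stride of encoder block ``i``; blocks beyond the
    strides list (the bottleneck when ``len(channels) == len(strides) + 1``)
    use stride 1.  Spatial extents must be divisible by the product of the
    strides.
    """

    in_channels: int = INITIAL_CHANNELS
    channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    strides: tuple[int, ...] = (1, 2, 2, 2)
    residual_units: int = 2
    out_channels: int = 1

    def __post_init__(self):
        object.__setattr__(self, "channels", tuple(self.channels))
        object.__setattr__(self, "strides", tuple(self.strides))
        if len(self.strides) > len(self.channels):
            raise ValueError("more strides than channel stages")
        if self.strides and self.strides[0] != 1:
            raise ValueError(
                "first stride must be 1 (full-resolution first stage)"
            )
        if self.out_channels != 1:
            raise ValueError("binary segmentation: out_channels must be 1")

    @property
    def stride_product(self) -> int:
        return int(np.prod(self.strides)) if self.strides else 1

    @classmethod
    def desk_scale(cls, in_channels: int = INITIAL_CHANNELS) -> "NetworkConfig":
        return cls(in_channels=in_channels, channels=(8, 16, 32), strides=(1, 2, 2))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(
            in_channels=d["in_channels"],
            channels=tuple(d["channels"]),
            strides=tuple(d["strides"]),
            residual_units=d.get("residual_units", 2),
            out_channels=d.get("out_channels", 1),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class SegmentationNetwork(nn.Module):
    """Residual 3D U-Net with a sigmoid-probability output.

    Encoder: one residual unit per channel stage, strided where the config
    says so.  Decoder: nearest-neighbour upsampling, skip concatenation, a
    1x1x1 channel projection and a residual unit per stage.  The head is a
    1x1x1 convolution producing one logit channel.
    """

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(seed)
        chans = config.channels
        n = len(chans)
        strides = [
            config.strides[i] if i < len(config.strides) else 1 for i in range(n)
        ]
        self._strides = strides
        cin = config.in_channels
        self.encoder = []
        for i in range(n):
            self.encoder.append(
                nn.ResidualUnit(cin, chans[i], strides[i], config.residual_units, rng, dtype)
            )
            cin = chans[i]
        self.decoder = []
        for i in range(n - 2, -1, -1):
            self.decoder.append(
                nn.UpBlock(
                    chans[i + 1], chans[i], chans[i], strides[i + 1],
                    config.residual_units, rng, dtype,
                )
            )
        self.head = nn.Conv3d(chans[0], config.out_channels, 1, 1, rng, dtype)
        self.dtype = dtype

    # -- forward ------------------------------------------------------------

    def _check_shape(self, shape: tuple[int, ...]) -> None:
        div = self.config.stride_product
        if any(s % div for s in shape):
            raise ValueError(
                f"spatial extents {shape} must be divisible by {div} "
                f"(product of strides {tuple(self._strides)})"
            )

    def forward_logits(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=self.dtype))
        if x.shape[0] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, got {x.shape[0]}"
            )
        self._check_shape(x.shape[1:])
        skips = []
        h = x
        for block in self.encoder:
            h = block(h)
            skips.append(h)
        for i, up in enumerate(self.decoder):
            skip = skips[len(self.encoder) - 2 - i]
            h = up(h, skip)
        return self.head(h)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference: sigmoid probabilities (H, W, D), graph-free."""
        with nn.no_grad():
            z = self.forward_logits(x)
        return _sigmoid(z.data[0]).astype(np.float32)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    """Build a network with deterministic initial parameters given
    ``(cfg, seed)``."""
    return SegmentationNetwork(cfg, seed)


def input_stack(
    pair: VolumePair,
    prev: ProbabilityVolume | None = None,
    channels: ClickChannels | None = None,
    mode: str = "initial",
) -> np.ndarray:
    """Assemble the multi-channel network input in the fixed channel order.

    ``mode``: ``'initial'`` -> [CT, PET]; ``'baseline'`` -> [CT, PET, pos,
    neg]; ``'refinement'`` -> [CT, PET, prev, pos, neg].
    """
    ct = pair.ct.data
    pet = pair.pet.data
    if mode == "initial":
        return np.stack([ct, pet]).astype(np.float32)
    if channels is None:
        raise ValueError(f"mode {mode!r} requires click channels")
    if channels.shape != pair.shape:
        raise ValueError("click channels shape mismatch")
    if mode == "baseline":
        return np.stack([ct, pet, channels.pos.data, channels.neg.data]).astype(np.float32)
    if mode == "refinement":
        if prev is None:
            raise ValueError("refinement mode requires the previous probability volume")
        if prev.shape != pair.shape:
            raise ValueError("previous probability shape mismatch")
        return np.stack(
            [ct, pet, prev.data, channels.pos.data, channels.neg.data]
        ).astype(np.float32)
    raise ValueError(f"unknown mode {mode!r}")


def save_checkpoint(
    net: SegmentationNetwork, path: str | Path, extra: dict | None = None
) -> None:
    """Store parameters, architecture config, and the build seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"config": net.config.to_dict(), "seed": net.seed}
    if extra:
        meta["extra"] = extra
    arrays = {k: v.data for k, v in net.named_parameters().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> SegmentationNetwork:
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        net = SegmentationNetwork(NetworkConfig.from_dict(meta["config"]), meta["seed"])
        params = net.named_parameters()
        for k, p in params.items():
            p.data = z[k].astype(p.data.dtype)
    return net
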