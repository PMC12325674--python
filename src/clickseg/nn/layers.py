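"""Layer modules for the residual 3D U-Net, built on the autodiff engine."""

from __future__ import annotations

import numpy as np

from .engine import Tensor, add, concat, conv3d, instance_norm, leaky_relu, upsample_nearest

__all__ = ["Module", "Conv3d", "InstanceNorm3d", "ResidualUnit", "UpBlock"]


class Module:
    """Base class: parameter collection and (de)serialization by name."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, v in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                out[key] = v
            elif isinstance(v, Module):
                out.update(v.named_parameters(f"{key}."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{i}."))
        return out


class Conv3d(Module):
    """3D convolution with He-style initialization."""

    def __init__(
        self,
        cin: int,
        cout: int,
        ksize: int,
        stride: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        fan_in = cin * ksize**3
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            (rng.standard_normal((cout, cin, ksize, ksize, ksize)) * scale).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(cout, dtype=dtype), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, dtype=np.float32, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, self.eps)


class ResidualUnit(Module):
    """``subunits`` conv->norm->LeakyReLU stages with a residual skip.

    The first conv carries the stride and the channel change; the skip path
    is a 1x1x1 strided conv whenever shapes differ, identity otherwise.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        stride: int,
        subunits: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        self.convs = []
        self.norms = []
        c = cin
        for i in range(max(1, subunits)):
            s = stride if i == 0 else 1
            self.convs.append(Conv3d(c, cout, 3, s, rng, dtype))
            self.norms.append(InstanceNorm3d(cout, dtype))
            c = cout
        if cin != cout or stride != 1:
            self.skip = Conv3d(cin, cout, 1, stride, rng, dtype)
        else:
            self.skip = None

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for i, (conv, norm) in enumerate(zip(self.convs, self.norms)):
            h = norm(conv(h))
            if i < len(self.convs) - 1:
                h = leaky_relu(h)
        res = x if self.skip is None else self.skip(x)
        return leaky_relu(add(h, res))


class UpBlock(Module):
    """Decoder stage: upsample, concatenate the encoder skip, mix channels
    with a 1x1x1 projection, then refine with a residual unit."""

    def __init__(
        self,
        c_deep: int,
        c_skip: int,
        cout: int,
        factor: int,
        subunits: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        self.factor = factor
        self.proj = Conv3d(c_deep + c_skip, cout, 1, 1, rng, dtype)
        self.proj_norm = InstanceNorm3d(cout, dtype)
        self.res = ResidualUnit(cout, cout, 1, subunits, rng, dtype)

    def __call__(self, deep: Tensor, skip: Tensor) -> Tensor:
        up = upsample_nearest(deep, self.factor)
        h = leaky_relu(self.proj_norm(self.proj(concat([up, skip]))))
        return self.res(h)
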