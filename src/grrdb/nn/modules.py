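"""Layer containers over :mod:`grrdb.nn.functional`.

Weights are created eagerly from a caller-supplied :class:`numpy.random.Generator`
(Kaiming fan-in scaling), so a model is a pure function of its config and seed.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter

DTYPE = np.float32


def kaiming(rng: np.random.Generator, shape, fan_in: int, gain: float = 1.0) -> np.ndarray:
    std = gain * np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(DTYPE)


class Module:
    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield name, v
            elif isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, (Parameter, Module)):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, v in self._children():
            full = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield full, v
            else:
                yield from v.named_parameters(full + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) - set(state)
            extra = set(state) - set(own)
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """Stride-1, same-padded convolution; odd kernel."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 bias: bool = True, zero_init: bool = False):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        fan_in = in_ch * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, in_ch, kernel, kernel), dtype=DTYPE)
        else:
            w = kaiming(rng, (out_ch, in_ch, kernel, kernel), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias)


class DepthwiseConv2d(Module):
    """Per-channel convolution with ``maps_per_channel`` outputs per channel."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator,
                 maps_per_channel: int = 1, dilation: int = 1, bias: bool = True):
        self.channels, self.kernel, self.dilation = channels, kernel, dilation
        self.maps_per_channel = maps_per_channel
        fan_in = kernel * kernel
        self.weight = Parameter(kaiming(rng, (channels, maps_per_channel, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(channels * maps_per_channel, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(kaiming(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, dtype=DTYPE)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return F.leaky_relu(x, self.slope)
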