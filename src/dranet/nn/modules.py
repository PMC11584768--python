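"""Layer modules over the autodiff core: parameter registry, init, state I/O."""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class; children and parameters are discovered from attributes."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: np.array(p.data) for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state: {sorted(missing)[:5]}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class GELU(Module):
    def forward(self, x):
        return F.gelu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, size=(in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None
        self.in_features, self.out_features = in_features, out_features

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    """3x3/1x1/7x7 convolution on channels-last maps; He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = False):
        fan_in = kernel * kernel * in_ch
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, size=(kernel, kernel, in_ch, out_ch)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = kernel // 2 if padding is None else padding
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel: int, rng: np.random.Generator, bias: bool = True):
        scale = np.sqrt(2.0 / (kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, scale, size=(kernel, kernel, channels)))
        self.bias = Parameter(np.zeros(channels)) if bias else None
        self.channels, self.kernel = channels, kernel

    def forward(self, x):
        return F.depthwise_conv2d(x, self.weight, self.bias, padding=self.kernel // 2)


class GroupNorm(Module):
    """Group normalization over channel groups of a channels-last map.

    Statistics are taken per sample over (H, W, C/G) inside each group, so
    the result is independent of batch size — the reason this network uses
    it at batch size 4.
    """

    def __init__(self, groups: int, channels: int, eps: float = 1e-5):
        if channels % groups:
            raise ValueError(f"channels {channels} not divisible by groups {groups}")
        self.groups, self.channels, self.eps = groups, channels, eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def forward(self, x):
        n, h, w, c = x.shape
        g = self.groups
        xg = F.reshape(x, (n, h, w, g, c // g))
        mu = F.mean(xg, axis=(1, 2, 4), keepdims=True)
        var = F.mean(F.power(xg - mu, 2.0), axis=(1, 2, 4), keepdims=True)
        xn = (xg - mu) * F.power(var + self.eps, -0.5)
        xn = F.reshape(xn, (n, h, w, c))
        return xn * self.weight + self.bias


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)
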