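"""Layer / module abstractions over the autograd core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import tensor as T
from .tensor import Tensor

_rng = np.random.default_rng(0)


def set_seed(seed: int) -> None:
    """Seed the global parameter-initialization RNG."""
    global _rng
    _rng = np.random.default_rng(seed)


class Module:
    """Base class: parameter registry, train/eval mode, recursion."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    """2-D convolution.

    Weights are drawn uniform on +/- 1/sqrt(fan_in), the conventional
    default of mainstream deep-learning frameworks for convolutional
    layers.  Batch normalization makes the forward pass insensitive to the
    init scale, while the modest magnitudes keep weights within reach of
    Adam's bounded per-coordinate displacement — which matters for short
    from-scratch training runs.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by "
                f"groups={groups}")
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kernel_size ** 2
        bound = np.float32(1.0 / np.sqrt(fan_in))
        shape = (out_channels, in_channels // groups, kernel_size, kernel_size)
        w = _rng.uniform(-bound, bound, shape).astype(np.float32)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Tensor(np.ones(num_features, np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(num_features, np.float32),
                           requires_grad=True)
        self.register_buffer("running_mean", np.zeros(num_features, np.float32))
        self.register_buffer("running_var", np.ones(num_features, np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return T.batchnorm2d(x, self.weight, self.bias, self.running_mean,
                             self.running_var, training=self.training,
                             momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return T.sigmoid(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.k, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return T.maxpool2d(x, self.k, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.k, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return T.avgpool2d(x, self.k, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def conv_bn_relu(cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int | None = None) -> Sequential:
    if padding is None:
        padding = k // 2
    return Sequential(Conv2d(cin, cout, k, stride, padding, bias=False),
                      BatchNorm2d(cout), ReLU())
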