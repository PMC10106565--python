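"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .exceptions import ConfigurationError


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # independent of any no_grad context at build time


class Module:
    """Base class: parameter registry, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    # buffers (non-trainable state such as BN running stats)
    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state["buffer:" + name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {name: None for name, _ in self.named_buffers()}
        for key, value in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                if name not in buffers:
                    raise KeyError(f"unexpected buffer {name!r} in checkpoint")
                obj, attr = self._resolve(name)
                setattr(obj, attr, np.asarray(value).copy())
            else:
                if key not in params:
                    raise KeyError(f"unexpected parameter {key!r} in checkpoint")
                if params[key].data.shape != value.shape:
                    raise ValueError(
                        f"parameter {key!r}: checkpoint shape {value.shape} does not "
                        f"match model shape {params[key].data.shape}")
                params[key].data = np.asarray(value).copy()
        missing = set(params) - {k for k in state if not k.startswith("buffer:")}
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:5]}")

    def _resolve(self, dotted: str):
        obj = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        return obj, parts[-1]


class ModuleList(list):
    """A list of sub-modules that the parameter registry traverses."""


def kaiming_uniform(rng: np.random.Generator, shape: tuple, fan_in: int,
                    dtype=np.float32) -> np.ndarray:
    bound = math.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if dilation < 1:
            raise ConfigurationError(f"dilation must be positive, got {dilation}")
        k = kernel_size
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.in_channels, self.out_channels = in_channels, out_channels
        fan_in = in_channels * k * k
        self.weight = Parameter(kaiming_uniform(rng, (out_channels, in_channels, k, k),
                                                fan_in, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ConfigurationError(
                f"Conv2d expected {self.in_channels} input channels, got {x.shape[1]}")
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.weight = Parameter(kaiming_uniform(rng, (in_features, out_features),
                                                in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self._buffer_names = ("running_mean", "running_var")

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.data.reshape(C))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.data.reshape(C))
            xhat = xc * ((var + self.eps) ** -0.5)
        else:
            mu = Tensor(self.running_mean.reshape(1, C, 1, 1))
            var = Tensor(self.running_var.reshape(1, C, 1, 1))
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, C, 1, 1) + self.beta.reshape(1, C, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6, dtype=np.float32):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, eps=self.eps)


class ConvBNReLU(Module):
    """3x3-style convolution followed by batch norm and ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, stride=stride,
                           padding=padding, dilation=dilation, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()
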