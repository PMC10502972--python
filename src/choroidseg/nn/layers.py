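"""Neural-network building blocks over the autograd engine."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as F
from .autograd import Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "BatchNorm2d", "ReLU", "Sigmoid",
    "MaxPool2d", "Upsample2x", "Identity",
]


class Module:
    """Base class: tracks parameters, sub-modules and the training flag."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        if not isinstance(x, Tensor):
            x = Tensor(x)
        return self.forward(x)

    def modules(self) -> Iterator["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_buffers(self) -> list[tuple[str, np.ndarray]]:
        """(path, array) pairs of non-trainable state (BN running stats)."""
        out = []
        for i, m in enumerate(self.modules()):
            for k, v in m.__dict__.items():
                if isinstance(v, np.ndarray):
                    out.append((f"{i}.{k}", v))
        return out

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # ---- flat (de)serialization in module-traversal order ------------- #
    def state_arrays(self) -> list[np.ndarray]:
        arrs = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Tensor) and v.requires_grad:
                    arrs.append(v.data)
                elif isinstance(v, np.ndarray):
                    arrs.append(v)
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        mine = self.state_arrays()
        if len(mine) != len(arrs):
            raise ValueError(
                f"checkpoint has {len(arrs)} arrays, model needs {len(mine)}"
            )
        for dst, src in zip(mine, arrs):
            if dst.shape != src.shape:
                raise ValueError("checkpoint array shape mismatch")
            dst[...] = src


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv2d(Module):
    """2-D convolution with He-normal initialization."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size,
        stride=1,
        padding=0,
        pad_mode: str = "zeros",
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        kh, kw = (kernel_size, kernel_size) if isinstance(
            kernel_size, int) else kernel_size
        self.stride = (stride, stride) if isinstance(stride, int) else stride
        self.padding = (padding, padding) if isinstance(
            padding, int) else padding
        self.pad_mode = pad_mode
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kh * kw
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.standard_normal((out_channels, in_channels, kh, kw)) * scale,
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(
            x, self.weight, self.bias,
            stride=self.stride, padding=self.padding, pad_mode=self.pad_mode,
        )


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.sigmoid(x)


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.maxpool2x2(x)


class Upsample2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        return F.upsample2x(x)


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x
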