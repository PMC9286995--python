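"""Parameterized layers on top of the autograd ops.

Convolutions that feed a batch-norm carry no bias.  Weight
initialization is He-style (std = sqrt(2 / fan_in)) from a caller-owned
numpy Generator so the whole network build is reproducible from one
seed.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in vars(self).values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def parameters(self) -> list[Tensor]:
        params = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Tensor) and v.requires_grad:
                    params.append(v)
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}

        def walk(mod, prefix):
            for name, v in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(v, Tensor) and v.requires_grad:
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-trainable state (batch-norm running statistics)."""
        out: dict[str, np.ndarray] = {}

        def walk(mod, prefix):
            for name, v in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(v, np.ndarray):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def param_count(self) -> int:
        """Exact number of trainable scalars."""
        return sum(p.size for p in self.parameters())

    def conv_weight_count(self) -> int:
        """Convolution kernel weights only (no BN affine terms, no biases)."""
        total = 0
        for m in self.modules():
            w = getattr(m, "weight", None)
            if isinstance(w, Tensor) and not isinstance(m, BatchNorm2d):
                total += w.size
        return total


def _he(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    std = np.sqrt(2.0 / fan_in)
    return Tensor(rng.normal(0.0, std, size=shape).astype(DTYPE), requires_grad=True)


class Conv3x3(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he(rng, (c_out, c_in, 3, 3), fan_in=9 * c_in)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3x3(x, self.weight)


class DepthwiseConv3x3(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he(rng, (channels, 3, 3), fan_in=9)

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise3x3(x, self.weight)


class Conv1x1(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = False):
        super().__init__()
        self.stride = stride
        self.weight = _he(rng, (c_out, c_in), fan_in=c_in)
        self.bias = Tensor(np.zeros(c_out, dtype=DTYPE), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv1x1(x, self.weight, bias=self.bias, stride=self.stride)


class ConvTranspose2x2(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _he(rng, (c_in, c_out, 2, 2), fan_in=4 * c_in)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2x2(x, self.weight)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.weight = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.bias_param = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm(
            x, self.weight, self.bias_param,
            self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class MaxPool2x2(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool2x2(x)
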