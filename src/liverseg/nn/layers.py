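"""Neural-network layers on top of the autodiff tensor.

Conventions follow the mainstream deep-learning frameworks: modules own
parameters, ``train()``/``eval()`` toggle batch-norm statistics and dropout,
and ``state_dict()`` round-trips all learnable state plus running buffers.
Batch normalization here carries *no* learnable affine pair — every norm in
these networks is followed by a biased convolution or linear layer, so the
scale/shift would be redundant and layer parameter counts stay equal to the
convolutional closed form ``Cin·K·Cout + Cout``.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "Sequential",
    "ModuleList",
    "Conv3d",
    "ConvTranspose3d",
    "Linear",
    "BatchNorm3d",
    "Dropout",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
    "count_parameters",
]


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    # ------------------------------------------------------------- traversal
    def children(self):
        for value in self.__dict__.values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self.children():
            yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            if isinstance(value, np.ndarray):
                yield f"{prefix}{name}", value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{prefix}{name}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{prefix}{name}.{i}.")

    # ------------------------------------------------------------------ mode
    def train(self, mode: bool = True):
        for module in self.modules():
            module.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # ----------------------------------------------------------------- state
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[f"buffer::{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer::"):
                buffers[key[len("buffer::"):]][...] = value
            else:
                params[key].data[...] = value


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.items = list(modules)

    def __iter__(self):
        return iter(self.items)

    def __len__(self):
        return len(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def append(self, module: Module):
        self.items.append(module)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        kernel = F._triple(kernel_size)
        fan_in = in_channels * int(np.prod(kernel))
        self.stride = F._triple(stride)
        self.padding = F._triple(padding)
        self.weight = Tensor(_he_init(rng, (out_channels, in_channels, *kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 output_padding=0, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        kernel = F._triple(kernel_size)
        fan_in = in_channels * int(np.prod(kernel))
        self.stride = F._triple(stride)
        self.padding = F._triple(padding)
        self.output_padding = F._triple(output_padding)
        self.weight = Tensor(_he_init(rng, (in_channels, out_channels, *kernel), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class Linear(Module):
    def __init__(self, in_features, out_features, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm3d(Module):
    """Per-channel normalization over (N, D, H, W); tracks running moments."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            return (x - mean) * ((var + self.eps) ** -0.5)
        shape = (1, -1, 1, 1, 1)
        mean = Tensor(self.running_mean.reshape(shape))
        scale = Tensor(1.0 / np.sqrt(self.running_var.reshape(shape) + self.eps))
        return (x - mean) * scale


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Seedable via ``reseed``."""

    def __init__(self, p: float = 0.2, seed: int = 0):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self._rng = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self._rng.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


def count_parameters(module: Module | None) -> int:
    """Exact number of trainable scalars reachable from ``module``."""
    if module is None:
        return 0
    return int(sum(p.size for p in module.parameters()))
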