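"""Neural-network layers and optimisation on top of :mod:`m3seg.autodiff`.

Follows the familiar Module/Parameter idiom: layers hold named parameters,
``Module.parameters()`` walks the attribute tree, and ``SGD`` implements
momentum + weight-decay stochastic gradient descent (the optimiser the
training protocol prescribes).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = [
    "Parameter",
    "Module",
    "ModuleList",
    "Linear",
    "Conv2d",
    "LayerNorm",
    "GroupNorm",
    "BatchNorm2d",
    "MLP",
    "SGD",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters are trainable even under no_grad


class Module:
    """Base class with recursive parameter/buffer discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    # attribute-scan registry: anything that is a Parameter, Module or
    # ModuleList found in __dict__ participates.
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, (Module, ModuleList)):
                yield from value.named_parameters(prefix=f"{key}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_modules(self, prefix: str = ""):
        yield prefix.rstrip("."), self
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_modules(prefix=f"{key}.")
            elif isinstance(value, ModuleList):
                for i, m in enumerate(value):
                    yield from m.named_modules(prefix=f"{key}.{i}.")

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor) and not isinstance(value, Parameter):
                yield key, value
            elif isinstance(value, (Module, ModuleList)):
                yield from value.named_buffers(prefix=f"{key}.")

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.data.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        for k, v in self.named_parameters():
            v.data = np.array(state[f"param:{k}"], dtype=np.float64)
        for k, v in self.named_buffers():
            v.data = np.array(state[f"buffer:{k}"], dtype=np.float64)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(list):
    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self):
            yield from m.named_parameters(prefix=f"{prefix}{i}.")

    def named_buffers(self, prefix: str = ""):
        for i, m in enumerate(self):
            yield from m.named_buffers(prefix=f"{prefix}{i}.")


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


def xavier_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=shape)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def norm_groups(channels: int, preferred: int = 8) -> int:
    """Largest divisor of ``channels`` that is <= ``preferred``."""
    import math

    g = math.gcd(preferred, channels)
    for cand in range(min(preferred, channels), 0, -1):
        if channels % cand == 0:
            return cand
    return g


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(xavier_uniform(rng, (in_features, out_features),
                                               in_features, out_features))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 groups: int = 1, bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}"
            )
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(kaiming_normal(
            rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.weight + self.bias


class GroupNorm(Module):
    """Normalise over (channel-group, H, W) per sample; input (B, C, H, W)."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError(f"channels {num_channels} not divisible by groups {num_groups}")
        self.num_groups = num_groups
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        g = self.num_groups
        xg = x.reshape(B, g, C // g, H, W)
        mu = xg.mean(axis=(2, 3, 4), keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=(2, 3, 4), keepdims=True)
        out = (xc / (var + self.eps).sqrt()).reshape(B, C, H, W)
        return out * self.weight.reshape(1, C, 1, 1) + self.bias.reshape(1, C, 1, 1)


class BatchNorm2d(Module):
    """Batch normalisation with a deterministic ``identity`` mode for fixtures.

    ``identity=True`` bypasses the statistics entirely (affine only), which
    gives tests a reproducible, batch-independent path.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 identity: bool = False):
        super().__init__()
        self.eps, self.momentum, self.identity = eps, momentum, identity
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))
        self.running_mean = Tensor(np.zeros(num_channels))
        self.running_var = Tensor(np.ones(num_channels))

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        w = self.weight.reshape(1, C, 1, 1)
        b = self.bias.reshape(1, C, 1, 1)
        if self.identity:
            return x * w + b
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mu.data.ravel()
            self.running_var.data = (1 - m) * self.running_var.data + m * var.data.ravel()
            return xc / (var + self.eps).sqrt() * w + b
        mu = self.running_mean.data.reshape(1, C, 1, 1)
        var = self.running_var.data.reshape(1, C, 1, 1)
        return (x - Tensor(mu)) / Tensor(np.sqrt(var + self.eps)) * w + b


class MLP(Module):
    """Transformer feed-forward block: Linear -> GELU -> Linear."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with momentum and decoupled L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.buffers = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, buf in zip(self.params, self.buffers):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {f"momentum:{i}": b.copy() for i, b in enumerate(self.buffers)}

    def load_state_dict(self, state: dict):
        for i in range(len(self.buffers)):
            self.buffers[i] = np.array(state[f"momentum:{i}"])
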