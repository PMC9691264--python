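"""Neural-network layers on top of the autodiff tape."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, conv1d_channels

__all__ = ["Module", "Parameter", "Conv2d", "BatchNorm2d", "ChannelConv1d"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal module container: parameter discovery and train/eval mode."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Parameter) and id(item) not in seen:
                    seen.add(id(item))
                    params.append(item)
                elif isinstance(item, Module):
                    for p in item.parameters():
                        if id(p) not in seen:
                            seen.add(id(p))
                            params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            items = v if isinstance(v, (list, tuple)) else [v]
            for item in items:
                if isinstance(item, Module):
                    mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        """Flat name -> array mapping of parameters and buffers."""
        out = {}
        for i, p in enumerate(self.parameters()):
            out[f"param_{i}"] = p.data.copy()
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                out[f"bn_{j}_mean"] = m.running_mean.copy()
                out[f"bn_{j}_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.data = np.asarray(state[f"param_{i}"], dtype=np.float32)
        for j, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"bn_{j}_mean"], np.float32)
                m.running_var = np.asarray(state[f"bn_{j}_var"], np.float32)

    def __call__(self, *args, **kw):
        return self.forward(*args, **kw)


class Conv2d(Module):
    """Stride-1 'same' convolution; He-normal weight init."""

    def __init__(self, cin: int, cout: int, k: int, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        std = float(np.sqrt(2.0 / (cin * k * k)))
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class BatchNorm2d(Module):
    """Per-channel batch normalization over (N, H, W).

    Train mode normalizes with batch statistics (gradients flow through
    them); eval mode uses exponential running averages.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Parameter(np.ones((1, c, 1, 1)))
        self.beta = Parameter(np.zeros((1, c, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, c, 1, 1), np.float32)
        self.running_var = np.ones((1, c, 1, 1), np.float32)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return self.gamma * xhat + self.beta


class ChannelConv1d(Module):
    """Kernel-3 zero-padded convolution along the channel axis of (N, C)."""

    def __init__(self, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.normal(0.0, np.sqrt(2.0 / 3.0), 3))
        self.bias = Parameter(np.zeros(1))

    def forward(self, x: Tensor) -> Tensor:
        return conv1d_channels(x, self.weight, self.bias)
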