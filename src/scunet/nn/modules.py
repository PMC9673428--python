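"""Layer objects holding learnable parameters.

Weights are He-uniform initialised (bound sqrt(6/fan_in)), biases zero.
Every module draws its initial weights from the ``numpy.random.Generator``
passed at construction, so a fixed seed gives bit-identical networks.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = ["Module", "Conv2d", "ConvTranspose2d", "BatchNorm2d", "Sequential"]


class Module:
    """Base class: recursive parameter discovery and train/eval switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    training: bool = True

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- flat (de)serialisation ------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All parameters and buffers keyed by a stable positional name."""
        out: dict[str, np.ndarray] = {}
        for i, m in enumerate(self.modules()):
            for attr in ("weight", "bias", "gamma", "beta",
                         "running_mean", "running_var"):
                v = getattr(m, attr, None)
                if isinstance(v, Tensor):
                    out[f"m{i}.{attr}"] = v.data
                elif isinstance(v, np.ndarray):
                    out[f"m{i}.{attr}"] = v
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self.modules()):
            for attr in ("weight", "bias", "gamma", "beta",
                         "running_mean", "running_var"):
                key = f"m{i}.{attr}"
                if key not in arrays:
                    continue
                v = getattr(m, attr)
                if isinstance(v, Tensor):
                    if v.data.shape != arrays[key].shape:
                        raise ValueError(
                            f"checkpoint shape {arrays[key].shape} != model "
                            f"shape {v.data.shape} for {key}")
                    v.data = arrays[key].astype(v.data.dtype)
                else:
                    setattr(m, attr, arrays[key].copy())


def _he_uniform(rng: np.random.Generator, shape, fan_in: int, dtype):
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 *, padding: int = 0, dilation: int = 1, stride: int = 1,
                 rng: np.random.Generator, dtype=np.float32):
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Tensor(_he_uniform(rng, (out_channels, in_channels, k, k),
                                         fan_in, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
        self.padding, self.dilation, self.stride = padding, dilation, stride

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class ConvTranspose2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 *, stride: int = 2, padding: int = 0, output_padding: int = 0,
                 rng: np.random.Generator, dtype=np.float32):
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Tensor(_he_uniform(rng, (in_channels, out_channels, k, k),
                                         fan_in, dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=dtype), requires_grad=True)
        self.stride, self.padding = stride, padding
        self.output_padding = output_padding

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, stride=self.stride,
                                  padding=self.padding,
                                  output_padding=self.output_padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with trainable affine parameters.

    Training mode normalises with batch statistics and updates running
    averages (momentum 0.1); evaluation mode uses the running averages.
    """

    def __init__(self, channels: int, *, eps: float = 1e-5,
                 momentum: float = 0.1, dtype=np.float32):
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            out, mu, var = F.batch_norm(x, self.gamma, self.beta, eps=self.eps)
            m = self.momentum
            nhw = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = nhw / max(nhw - 1, 1)
            self.running_mean = (1 - m) * self.running_mean + m * mu
            self.running_var = (1 - m) * self.running_var + m * unbias * var
            return out
        mu = self.running_mean.reshape(shape)
        sd = np.sqrt(self.running_var.reshape(shape) + self.eps)
        xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x
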