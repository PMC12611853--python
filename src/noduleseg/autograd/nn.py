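"""Layer/module abstractions over the autograd tensor core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import DTYPE, Tensor
from . import functional as F


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, tensor: Tensor) -> Tensor:
        tensor.requires_grad = True
        self._params[name] = tensor
        object.__setattr__(self, name, tensor)
        return tensor

    def register_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        self._buffers[name] = array
        object.__setattr__(self, name, array)
        return array

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def parameters(self) -> Iterator[Tensor]:
        for m in self.modules():
            yield from m._params.values()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for mod_name, m in self._modules.items():
            yield from m.named_parameters(prefix + mod_name + ".")

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mod_name, m in self._modules.items():
            yield from m.named_buffers(prefix + mod_name + ".")

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=DTYPE).reshape(p.data.shape)
        for name, _ in self.named_buffers():
            arr = np.asarray(state[name])
            # locate the owner to replace the attribute as well
            owner = self
            parts = name.split(".")
            for part in parts[:-1]:
                owner = owner._modules[part]
            owner.register_buffer(parts[-1], arr.astype(owner._buffers[parts[-1]].dtype))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


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


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel, stride=1, padding=0,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel counts must be >= 1")
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        fan_in = in_ch * kh * kw
        self.register_parameter("weight", Tensor(_he_normal(rng, (out_ch, in_ch, kh, kw), fan_in)))
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_ch, dtype=DTYPE)))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    """Upsampling transposed convolution with kernel_size == stride."""

    def __init__(self, in_ch: int, out_ch: int, stride: int = 2,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.register_parameter(
            "weight", Tensor(_he_normal(rng, (in_ch, out_ch, stride, stride), in_ch))
        )
        if bias:
            self.register_parameter("bias", Tensor(np.zeros(out_ch, dtype=DTYPE)))
        else:
            self.bias = None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics.

    Training mode normalizes by batch statistics and updates exponential
    running averages (momentum 0.1); evaluation mode uses the running values,
    making inference deterministic and batch-independent.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.eps, self.momentum = eps, momentum
        self.register_parameter("gamma", Tensor(np.ones(channels, dtype=DTYPE)))
        self.register_parameter("beta", Tensor(np.zeros(channels, dtype=DTYPE)))
        self.register_buffer("running_mean", np.zeros(channels, dtype=DTYPE))
        self.register_buffer("running_var", np.ones(channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            out, mu, var = F.batchnorm_train(x, self.gamma, self.beta, self.eps)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            return out
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
        var = Tensor(self.running_var.reshape(1, c, 1, 1))
        return gamma * ((x - mu) / (var + self.eps).sqrt()) + beta


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return F.max_pool2d(x, self.kernel, self.stride, self.padding)


class Lambda(Module):
    """Wrap a stateless tensor function (e.g. an activation) as a module."""

    def __init__(self, fn):
        super().__init__()
        self.fn = fn

    def forward(self, x: Tensor) -> Tensor:
        return self.fn(x)
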