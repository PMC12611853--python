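"""Activation-function registry.

All activations operate elementwise on either plain numpy arrays/scalars or
autograd :class:`~noduleseg.autograd.Tensor` objects, and every registered
function is monotone non-decreasing on [0, inf).

GELU weights its input by the standard-normal CDF,

    f(i) = 0.5 * i * (1 + erf(i / sqrt(2))),

and the faster tanh surrogate

    erf(i / sqrt(2)) ~= tanh(sqrt(2/pi) * (i + 0.044715 * i^3))

is registered as the ``gelu_tanh`` variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .autograd import Tensor

_SQRT_2 = float(np.sqrt(2.0))
_SQRT_2_OVER_PI = float(np.sqrt(2.0 / np.pi))

# canonical self-normalizing constants
_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def relu(x: Tensor) -> Tensor:
    return x.maximum(0.0)


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    return x.maximum(0.0) + slope * x.minimum(0.0)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    # exp(min(x, 0)) - 1 vanishes on x >= 0, so the two pieces join smoothly
    return x.maximum(0.0) + alpha * (x.minimum(0.0).exp() - 1.0)


def selu(x: Tensor) -> Tensor:
    return _SELU_SCALE * elu(x, alpha=_SELU_ALPHA)


def gelu(x: Tensor) -> Tensor:
    return 0.5 * x * ((x * (1.0 / _SQRT_2)).erf() + 1.0)


def gelu_tanh(x: Tensor) -> Tensor:
    inner = _SQRT_2_OVER_PI * (x + 0.044715 * (x * x * x))
    return 0.5 * x * (inner.tanh() + 1.0)


def softplus(x: Tensor) -> Tensor:
    # overflow-safe: max(x, 0) + log(1 + exp(-|x|))
    return x.maximum(0.0) + ((-x.abs()).exp() + 1.0).log()


def mish(x: Tensor) -> Tensor:
    return x * softplus(x).tanh()


def swish(x: Tensor) -> Tensor:
    return x * x.sigmoid()


@dataclass(frozen=True)
class ActivationSpec:
    """Named activation with optional shape parameters.

    ``params`` may carry ``slope`` (LeakyReLU, must be > 0) or ``alpha`` (ELU).
    """

    name: str = "gelu"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        key = self.name.lower()
        if key not in REGISTRY:
            raise KeyError(
                f"unknown activation {self.name!r}; registered: {sorted(REGISTRY)}"
            )
        if key == "leakyrelu" and self.params.get("slope", 0.01) <= 0:
            raise ValueError("LeakyReLU slope must be positive")

    def fn(self) -> Callable[[Tensor], Tensor]:
        key = self.name.lower()
        if key == "leakyrelu":
            slope = self.params.get("slope", 0.01)
            return lambda x: leaky_relu(x, slope)
        if key == "elu":
            alpha = self.params.get("alpha", 1.0)
            return lambda x: elu(x, alpha)
        return REGISTRY[key]


REGISTRY: dict[str, Callable[[Tensor], Tensor]] = {
    "selu": selu,
    "elu": elu,
    "gelu": gelu,
    "gelu_tanh": gelu_tanh,
    "mish": mish,
    "swish": swish,
    "relu": relu,
    "leakyrelu": leaky_relu,
}


def activation(spec: ActivationSpec | str, x):
    """Apply a registered activation to a scalar, ndarray or Tensor."""
    if isinstance(spec, str):
        spec = ActivationSpec(spec)
    fn = spec.fn()
    if isinstance(x, Tensor):
        return fn(x)
    arr = np.asarray(x, dtype=np.float32)
    out = fn(Tensor(arr)).data
    return out.item() if np.isscalar(x) or arr.ndim == 0 else out
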