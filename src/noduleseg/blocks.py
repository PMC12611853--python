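"""Reusable network building blocks.

* :class:`MultiScaleBlock` — parallel 3x3 and 7x7 convolution paths fused by a
  1x1 convolution, giving each stage both a fine and a broad receptive field.
* :class:`ACB` — asymmetric convolution block: the sum of 3x3, 1x3 and 3x1
  branches emphasizes the kernel's central cross, followed by batch
  normalization and a nonlinearity.
* :class:`ChannelAttention` — squeeze/restore channel reweighting driven by
  global average- and max-pooled descriptors, CBAM-style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .activations import ActivationSpec
from .autograd import Tensor, concatenate
from .autograd import functional as F
from .autograd.nn import BatchNorm2d, Conv2d, Module


@dataclass(frozen=True)
class BlockParams:
    """Channel configuration shared by the convolutional blocks."""

    in_channels: int
    out_channels: int
    bn_eps: float = 1e-5
    bn_momentum: float = 0.1

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        if self.bn_eps <= 0:
            raise ValueError("bn_eps must be positive")


class MultiScaleBlock(Module):
    """Two same-padded convolution paths (3x3 and 7x7), each batch-normed and
    activated, concatenated and fused to ``out_channels`` by a 1x1 conv."""

    def __init__(self, in_ch: int, out_ch: int,
                 act: ActivationSpec | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        act = act or ActivationSpec("gelu")
        rng = rng or np.random.default_rng()
        self._act = act.fn()
        self.conv3 = Conv2d(in_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)
        self.conv7 = Conv2d(in_ch, out_ch, 7, padding=3, bias=False, rng=rng)
        self.bn7 = BatchNorm2d(out_ch)
        self.fuse = Conv2d(2 * out_ch, out_ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        p3 = self._act(self.bn3(self.conv3(x)))
        p7 = self._act(self.bn7(self.conv7(x)))
        return self.fuse(concatenate([p3, p7], axis=1))


class ACB(Module):
    """Asymmetric convolution block.

    The branch sum ``F3x3(x) + F1x3(x) + F3x1(x)`` is algebraically a single
    3x3 convolution whose kernel is the square kernel plus the horizontal
    kernel embedded in the middle row and the vertical kernel embedded in the
    middle column; :meth:`fused_kernel` materializes it.  Batch normalization
    and the activation follow the sum.
    """

    def __init__(self, in_ch: int, out_ch: int,
                 act: ActivationSpec | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        act = act or ActivationSpec("gelu")
        rng = rng or np.random.default_rng()
        self._act = act.fn()
        self.conv_sq = Conv2d(in_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.conv_h = Conv2d(in_ch, out_ch, (1, 3), padding=(0, 1), bias=False, rng=rng)
        self.conv_v = Conv2d(in_ch, out_ch, (3, 1), padding=(1, 0), bias=False, rng=rng)
        self.bn = BatchNorm2d(out_ch)

    def branch_sum(self, x: Tensor) -> Tensor:
        """The pre-normalization three-branch sum."""
        return self.conv_sq(x) + self.conv_h(x) + self.conv_v(x)

    def fused_kernel(self) -> np.ndarray:
        """Single 3x3 kernel equivalent to the three branches."""
        k = self.conv_sq.weight.data.copy()
        k[:, :, 1:2, :] += self.conv_h.weight.data
        k[:, :, :, 1:2] += self.conv_v.weight.data
        return k

    def forward(self, x: Tensor) -> Tensor:
        return self._act(self.bn(self.branch_sum(x)))


class ChannelAttention(Module):
    """Channel attention block (ChAB).

    A 1x1 convolution first maps the input to ``reduce_channels``.  Global
    average- and max-pooled channel descriptors each pass through their own
    squeeze (to ``reduce_channels / ratio``) and restore convolutions; the two
    restored vectors are summed and squashed by a sigmoid into per-channel
    weights in (0, 1) that rescale the reduced map.
    """

    def __init__(self, in_ch: int, reduce_channels: int, ratio: int = 16,
                 act: ActivationSpec | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if reduce_channels % ratio != 0:
            raise ValueError(
                f"reduce_channels ({reduce_channels}) must be divisible by the "
                f"squeeze ratio ({ratio})"
            )
        act = act or ActivationSpec("gelu")
        rng = rng or np.random.default_rng()
        self._act = act.fn()
        squeeze = reduce_channels // ratio
        self.ratio = ratio
        self.reduce_channels = reduce_channels
        self.squeeze_channels = squeeze
        self.reduce = Conv2d(in_ch, reduce_channels, 1, rng=rng)
        self.avg_squeeze = Conv2d(reduce_channels, squeeze, 1, rng=rng)
        self.avg_restore = Conv2d(squeeze, reduce_channels, 1, rng=rng)
        self.max_squeeze = Conv2d(reduce_channels, squeeze, 1, rng=rng)
        self.max_restore = Conv2d(squeeze, reduce_channels, 1, rng=rng)

    def attention_logits(self, reduced: Tensor) -> Tensor:
        """Pre-sigmoid sum of the two pooling branches."""
        a = self.avg_restore(self._act(self.avg_squeeze(F.avg_pool_global(reduced))))
        m = self.max_restore(self._act(self.max_squeeze(F.max_pool_global(reduced))))
        return a + m

    def forward(self, x: Tensor) -> Tensor:
        reduced = self.reduce(x)
        weights = self.attention_logits(reduced).sigmoid()
        return reduced * weights
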