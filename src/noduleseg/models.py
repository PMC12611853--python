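"""The three segmentation architectures.

* :class:`MultiScaleUNet` — UNet whose encoder/decoder stages are
  :class:`~noduleseg.blocks.MultiScaleBlock`\\ s (parallel 3x3/7x7 paths).
* :class:`ACBUNet` — five-level UNet with asymmetric convolution blocks,
  multi-scale skip fusion and channel attention.
* :class:`FPNLinearAttention` — ResNet-34 bottom-up pathway, FPN top-down
  pathway with lateral connections, linear-attention aggregation of P2..P5
  and a segmentation head.

All models map a grayscale batch (B, in_channels, H, W) to a probability map
of the same spatial size with values in (0, 1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .activations import ActivationSpec
from .attention import AttentionAggregation
from .autograd import Tensor, concatenate
from .autograd import functional as F
from .autograd.nn import (BatchNorm2d, Conv2d, ConvTranspose2d, MaxPool2d,
                          Module, Sequential)
from .blocks import ACB, ChannelAttention, MultiScaleBlock

ARCHITECTURES = ("msunet", "acb_unet", "fpn_la")


@dataclass
class ModelConfig:
    """Architecture selection and hyperparameters.

    ``pretrained_backbone`` is off by default: the ResNet-34 bottom-up
    pathway trains from scratch.  Previously trained weights are restored
    through :func:`load_checkpoint` rather than downloaded.
    """

    architecture: str = "fpn_la"
    in_channels: int = 1
    base_width: int = 32
    levels: int = 5
    activation: ActivationSpec = field(default_factory=lambda: ActivationSpec("gelu"))
    pyramid_width: int = 64
    pretrained_backbone: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"architecture must be one of {ARCHITECTURES}")
        if self.levels < 3:
            raise ValueError("levels must be >= 3")
        if isinstance(self.activation, str):
            self.activation = ActivationSpec(self.activation)
        if isinstance(self.activation, dict):
            self.activation = ActivationSpec(**self.activation)


@dataclass
class PyramidFeatures:
    """Bottom-up maps at 1/4, 1/8, 1/16 and 1/32 of the input size.

    The stride-2 stage F1 is never stored — only F2..F5 enter the pyramid.
    """

    f2: Tensor
    f3: Tensor
    f4: Tensor
    f5: Tensor


def _check_divisible(hw: tuple[int, int], factor: int, arch: str) -> None:
    if hw[0] % factor or hw[1] % factor:
        raise ValueError(
            f"{arch} requires input spatial dims divisible by {factor}, got {hw}"
        )


# --------------------------------------------------------------------------
# Multi-scale UNet
# --------------------------------------------------------------------------
class MultiScaleUNet(Module):
    """Encoder-decoder of multi-scale blocks with concatenating skips.

    Encoder widths (32, 64, 128, 256) with a 512-channel bottleneck; 2x2
    max-pool downsampling.  The decoder upsamples with transposed
    convolutions into half-width multi-scale blocks (128, 64, 32, 16) — a
    light decoder in the style of modern segmentation libraries, keeping the
    architecture deliberately inexpensive — followed by a 1x1 convolution
    and sigmoid.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        act = config.activation
        w = config.base_width
        widths = [w, 2 * w, 4 * w, 8 * w]
        bott = 16 * w
        self.widths = widths
        self.depth = len(widths)
        self.pool = MaxPool2d(2)

        enc_in = [config.in_channels] + widths[:-1]
        self.enc = [MultiScaleBlock(i, o, act, rng) for i, o in zip(enc_in, widths)]
        for j, m in enumerate(self.enc):
            self._modules[f"enc{j}"] = m
        self.bottleneck = MultiScaleBlock(widths[-1], bott, act, rng)

        ups, decs = [], []
        prev = bott
        for width in reversed(widths):
            dec_w = max(width // 2, 8)
            ups.append(ConvTranspose2d(prev, dec_w, 2, rng=rng))
            decs.append(MultiScaleBlock(dec_w + width, dec_w, act, rng))
            prev = dec_w
        self.ups, self.decs = ups, decs
        for j, (u, d) in enumerate(zip(ups, decs)):
            self._modules[f"up{j}"] = u
            self._modules[f"dec{j}"] = d
        self.head = Conv2d(prev, 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        _check_divisible(x.shape[2:], 2**self.depth, "msunet")
        skips = []
        h = x
        for enc in self.enc:
            h = enc(h)
            skips.append(h)
            h = self.pool(h)
        h = self.bottleneck(h)
        for up, dec, skip in zip(self.ups, self.decs, reversed(skips)):
            h = dec(concatenate([up(h), skip], axis=1))
        return self.head(h).sigmoid()


# --------------------------------------------------------------------------
# UNet with ACBs, multi-scale skip fusion and channel attention
# --------------------------------------------------------------------------
class MultiScaleSkipFusion(Module):
    """Produce decoder map ID_j from all encoder and deeper decoder maps.

    Branch A (down-gathering): encoder maps above level j are max-pooled to
    level-j resolution, 1x1-projected to the level width, summed together
    with IE_j, and passed through an ACB.  Branch B (up-gathering): deeper
    decoder maps are upsampled by transposed convolutions straight to the
    level width and resolution, summed, and passed through an ACB.  The two
    branches are concatenated and a channel attention block emits ID_j.

    At the deepest level the decoder map is the encoder map itself.
    """

    def __init__(self, level: int, widths: list[int], act: ActivationSpec,
                 rng: np.random.Generator):
        super().__init__()
        j = level  # 1-based, 1 = finest
        self.level = j
        self.n_levels = len(widths)
        wj = widths[j - 1]
        self.down_proj = []
        for k in range(1, j):
            proj = Conv2d(widths[k - 1], wj, 1, rng=rng)
            self.down_proj.append(proj)
            self._modules[f"down_proj{k}"] = proj
        self.acb_down = ACB(wj, wj, act, rng)
        self.up_tc = []
        for k in range(j + 1, self.n_levels + 1):
            # cascade of stride-2 transposed convs; the first stage drops the
            # channel count so later (higher-resolution) stages stay cheap
            stages = [ConvTranspose2d(widths[k - 1], wj, 2, rng=rng)]
            stages += [ConvTranspose2d(wj, wj, 2, rng=rng) for _ in range(k - j - 1)]
            tc = Sequential(*stages)
            self.up_tc.append(tc)
            self._modules[f"up_tc{k}"] = tc
        self.acb_up = ACB(wj, wj, act, rng)
        self.chab = ChannelAttention(2 * wj, wj, ratio=16, act=act, rng=rng)

    def forward(self, encoder_maps: list[Tensor], deeper_decoder_maps: list[Tensor]) -> Tensor:
        j = self.level
        target_hw = encoder_maps[j - 1].shape[2:]
        down = encoder_maps[j - 1]
        for k, proj in enumerate(self.down_proj, start=1):
            pooled = F.max_pool2d(encoder_maps[k - 1], 2 ** (j - k))
            down = down + proj(pooled)
        a = self.acb_down(down)

        up = None
        for tc, dk in zip(self.up_tc, deeper_decoder_maps):
            u = tc(dk)
            if u.shape[2:] != target_hw:
                raise ValueError(
                    f"skip fusion level {j}: upsampled map has spatial size "
                    f"{u.shape[2:]}, expected {target_hw}"
                )
            up = u if up is None else up + u
        b = self.acb_up(up)
        return self.chab(concatenate([a, b], axis=1))


class ACBUNet(Module):
    """Five-level UNet with ACB encoders and attention-fused skips."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        act = config.activation
        w = config.base_width
        m = config.levels
        widths = [w * 2**i for i in range(m)]
        self.widths = widths
        self.levels = m
        self.pool = MaxPool2d(2)
        enc_in = [config.in_channels] + widths[:-1]
        self.enc = [ACB(i, o, act, rng) for i, o in zip(enc_in, widths)]
        for j, mod in enumerate(self.enc, start=1):
            self._modules[f"enc{j}"] = mod
        self.fusion = [MultiScaleSkipFusion(j, widths, act, rng) for j in range(1, m)]
        for j, mod in enumerate(self.fusion, start=1):
            self._modules[f"fusion{j}"] = mod
        self.head = Conv2d(widths[0], 1, 1, rng=rng)

    def encoder_maps(self, x: Tensor) -> list[Tensor]:
        maps = []
        h = x
        for j, enc in enumerate(self.enc):
            if j > 0:
                h = self.pool(h)
            h = enc(h)
            maps.append(h)
        return maps

    def decoder_maps(self, encoder_maps: list[Tensor]) -> list[Tensor]:
        m = self.levels
        decoder: dict[int, Tensor] = {m: encoder_maps[m - 1]}  # ID_M = IE_M
        for j in range(m - 1, 0, -1):
            deeper = [decoder[k] for k in range(j + 1, m + 1)]
            decoder[j] = self.fusion[j - 1](encoder_maps, deeper)
        return [decoder[j] for j in range(1, m + 1)]

    def forward(self, x: Tensor) -> Tensor:
        _check_divisible(x.shape[2:], 2 ** (self.levels - 1), "acb_unet")
        enc = self.encoder_maps(x)
        dec = self.decoder_maps(enc)
        return self.head(dec[0]).sigmoid()


# --------------------------------------------------------------------------
# FPN with linear attention
# --------------------------------------------------------------------------
class BasicBlock(Module):
    """ResNet basic residual block (two 3x3 convolutions)."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 act: ActivationSpec, rng: np.random.Generator):
        super().__init__()
        self._act = act.fn()
        self.conv1 = Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, padding=1, bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.short_conv = Conv2d(in_ch, out_ch, 1, stride=stride, bias=False, rng=rng)
            self.short_bn = BatchNorm2d(out_ch)
        else:
            self.short_conv = None

    def forward(self, x: Tensor) -> Tensor:
        h = self._act(self.bn1(self.conv1(x)))
        h = self.bn2(self.conv2(h))
        s = x if self.short_conv is None else self.short_bn(self.short_conv(x))
        return self._act(h + s)


class ResNet34BottomUp(Module):
    """ResNet-34 feature extractor emitting F2..F5.

    Stage widths (64, 128, 256, 512) with (3, 4, 6, 3) basic blocks; the
    7x7/stride-2 stem plus 3x3/stride-2 max-pool put F2 at 1/4 of the input.
    Trained from scratch (no downloaded weights).
    """

    STAGE_WIDTHS = (64, 128, 256, 512)
    STAGE_BLOCKS = (3, 4, 6, 3)

    def __init__(self, in_ch: int, act: ActivationSpec, rng: np.random.Generator):
        super().__init__()
        self._act = act.fn()
        self.stem = Conv2d(in_ch, 64, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(64)
        self.stem_pool = MaxPool2d(3, 2, 1)
        self.stages = []
        prev = 64
        for s, (width, nblocks) in enumerate(zip(self.STAGE_WIDTHS, self.STAGE_BLOCKS)):
            blocks = []
            for i in range(nblocks):
                stride = 2 if (i == 0 and s > 0) else 1
                blocks.append(BasicBlock(prev, width, stride, act, rng))
                prev = width
            self.stages.append(blocks)
            for i, blk in enumerate(blocks):
                self._modules[f"stage{s}_{i}"] = blk

    def forward(self, x: Tensor) -> PyramidFeatures:
        _check_divisible(x.shape[2:], 32, "fpn_la")
        h = self.stem_pool(self._act(self.stem_bn(self.stem(x))))
        outs = []
        for blocks in self.stages:
            for blk in blocks:
                h = blk(h)
            outs.append(h)
        return PyramidFeatures(*outs)


class FPNTopDown(Module):
    """Lateral 1x1 connections plus nearest-neighbour top-down merging.

    M5 = lat5(F5); M_i = lat_i(F_i) + upsample2(M_{i+1}); each P_i is a 3x3
    anti-aliasing convolution of M_i (applied to M5 as well so that P5 exists
    for aggregation).  All P maps have ``pyramid_width`` channels.
    """

    def __init__(self, in_widths=(64, 128, 256, 512), d: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.d = d
        self.lateral = [Conv2d(wi, d, 1, rng=rng) for wi in in_widths]
        self.smooth = [Conv2d(d, d, 3, padding=1, rng=rng) for _ in in_widths]
        for i, (l, s) in enumerate(zip(self.lateral, self.smooth)):
            self._modules[f"lateral{i}"] = l
            self._modules[f"smooth{i}"] = s

    def forward(self, feats: PyramidFeatures) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        f = [feats.f2, feats.f3, feats.f4, feats.f5]
        m = [None] * 4
        m[3] = self.lateral[3](f[3])
        for i in (2, 1, 0):
            m[i] = self.lateral[i](f[i]) + F.upsample_nearest(m[i + 1], 2)
        p = [self.smooth[i](m[i]) for i in range(4)]
        return tuple(p)


class FPNLinearAttention(Module):
    """FPN with linear-attention aggregation and a segmentation head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        act = config.activation
        d = config.pyramid_width
        self._act = act.fn()
        self.backbone = ResNet34BottomUp(config.in_channels, act, rng)
        self.top_down = FPNTopDown(ResNet34BottomUp.STAGE_WIDTHS, d, rng)
        self.aggregation = AttentionAggregation(d, rng=rng)
        self.head_conv = Conv2d(4 * d, d, 3, padding=1, rng=rng)
        self.head_bn = BatchNorm2d(d)
        self.head_out = Conv2d(d, 1, 1, rng=rng)

    def bottom_up(self, x: Tensor) -> PyramidFeatures:
        return self.backbone(x)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2:]
        feats = self.bottom_up(x)
        p2, p3, p4, p5 = self.top_down(feats)
        agg = self.aggregation(p2, p3, p4, p5)
        y = self._act(self.head_bn(self.head_conv(agg)))
        y = F.upsample_bilinear(y, (h, w))
        return self.head_out(y).sigmoid()


# --------------------------------------------------------------------------
# factory and checkpointing
# --------------------------------------------------------------------------
def build_model(config: ModelConfig) -> Module:
    cls = {
        "msunet": MultiScaleUNet,
        "acb_unet": ACBUNet,
        "fpn_la": FPNLinearAttention,
    }[config.architecture]
    return cls(config)


_CHECKPOINT_VERSION = 1


def save_checkpoint(model: Module, config: ModelConfig, path: str | Path) -> None:
    """Write weights (.npz) with a JSON sidecar carrying the model config."""
    path = Path(path)
    with open(path, "wb") as fh:
        np.savez(fh, **model.state_dict())
    manifest = {
        "version": _CHECKPOINT_VERSION,
        "config": {**asdict(config), "activation": {
            "name": config.activation.name, "params": config.activation.params}},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> tuple[Module, ModelConfig]:
    path = Path(path)
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["activation"] = ActivationSpec(**cfg_dict["activation"])
    config = ModelConfig(**cfg_dict)
    model = build_model(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, config
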