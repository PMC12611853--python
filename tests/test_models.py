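"""Architecture contracts: shapes, determinism, ablations, learning signal."""

import numpy as np
import pytest

from noduleseg.activations import ActivationSpec
from noduleseg.autograd import Tensor
from noduleseg.autograd.optim import Adam
from noduleseg.models import (ACBUNet, FPNLinearAttention, ModelConfig,
                              MultiScaleUNet, ResNet34BottomUp, build_model,
                              load_checkpoint, save_checkpoint)
from noduleseg.train_eval import TrainConfig, bce_dice_loss

ARCHS = ["msunet", "acb_unet", "fpn_la"]


def _model(arch, seed=0, act="gelu"):
    return build_model(ModelConfig(architecture=arch, seed=seed,
                                   activation=ActivationSpec(act)))


@pytest.fixture(scope="module")
def batch(small_phantom):
    img = small_phantom.image[None, None].astype(np.float32)
    mask = small_phantom.nodule_mask[None, None].astype(np.float32)
    return img, mask


@pytest.mark.parametrize("arch", ARCHS)
def test_forward_contract_probability_map(arch, batch):
    model = _model(arch)
    model.train()
    out = model(Tensor(batch[0]))  # batch-norm uses batch statistics
    assert out.shape == batch[0].shape
    assert (out.data > 0).all() and (out.data < 1).all()
    model.eval()  # with warmed running stats the eval path stays in range
    out_eval = model(Tensor(batch[0]))
    assert out_eval.shape == batch[0].shape
    assert (out_eval.data >= 0).all() and (out_eval.data <= 1).all()


@pytest.mark.parametrize("arch", ARCHS)
def test_eval_mode_deterministic(arch, batch):
    model = _model(arch).eval()
    a = model(Tensor(batch[0])).data
    b = model(Tensor(batch[0])).data
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize("arch", ARCHS)
def test_indivisible_input_rejected(arch):
    model = _model(arch)
    with pytest.raises(ValueError, match="divisible"):
        model(Tensor(np.zeros((1, 1, 50, 50), dtype=np.float32)))


@pytest.mark.parametrize("arch", ARCHS)
def test_single_step_decreases_training_loss(arch, batch):
    model = _model(arch)
    cfg = TrainConfig(epochs=1, learning_rate=1e-4)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.train()
    x = Tensor(batch[0])
    before = bce_dice_loss(model(x), batch[1], cfg)
    before.backward()
    opt.step()
    after = bce_dice_loss(model(x), batch[1], cfg)
    assert float(after.data) < float(before.data)


@pytest.mark.parametrize("arch", ARCHS)
@pytest.mark.parametrize("act", ["gelu", "leakyrelu", "elu", "mish"])
def test_gradient_reaches_every_parameter(arch, act):
    model = _model(arch, act=act)
    rng = np.random.default_rng(0)
    x = Tensor(rng.standard_normal((2, 1, 32, 32)).astype(np.float32))
    target = (rng.random((2, 1, 32, 32)) < 0.1).astype(np.float32)
    model.train()
    loss = bce_dice_loss(model(x), target, TrainConfig(epochs=1))
    loss.backward()
    dead = [n for n, p in model.named_parameters()
            if p.grad is None or not np.any(p.grad)]
    assert not dead, f"parameters with zero gradient: {dead[:5]}"


# -- multi-scale skip fusion -----------------------------------------------
def test_skip_fusion_identity_at_deepest_level():
    model = _model("acb_unet").eval()
    x = Tensor(np.random.default_rng(1).standard_normal((1, 1, 32, 32)).astype(np.float32))
    enc = model.encoder_maps(x)
    dec = model.decoder_maps(enc)
    np.testing.assert_array_equal(dec[-1].data, enc[-1].data)  # ID_M = IE_M


def test_skip_fusion_shapes_and_zero_deeper_branch():
    model = _model("acb_unet").eval()
    x = Tensor(np.random.default_rng(2).standard_normal((1, 1, 32, 32)).astype(np.float32))
    enc = model.encoder_maps(x)
    dec = model.decoder_maps(enc)
    for j, d in enumerate(dec[:-1], start=1):
        assert d.shape[2:] == enc[j - 1].shape[2:]
        assert d.shape[1] == model.widths[j - 1]
    # zero deeper decoder maps: fusion still well-defined with correct shape
    fusion = model.fusion[-1]  # level M-1
    deeper = [Tensor(np.zeros_like(dec[-1].data))]
    out = fusion(enc, deeper)
    assert out.shape == dec[-2].shape


def test_id3_channel_attention_has_128_filters():
    model = _model("acb_unet")
    chab3 = model.fusion[2].chab  # level 3
    assert chab3.reduce.weight.shape[0] == 128
    assert chab3.reduce_channels // chab3.squeeze_channels == 16


# -- ACB fused-kernel equivalence across the whole network ------------------
def test_acb_unet_fused_kernel_network_equivalence(batch):
    model = _model("acb_unet")
    x = Tensor(batch[0])
    model.train()
    model(x)  # warm batch-norm running statistics
    model.eval()
    ref = model(x).data
    for mod in model.modules():
        if hasattr(mod, "fused_kernel"):
            mod.conv_sq.weight.data = mod.fused_kernel()
            mod.conv_h.weight.data[:] = 0.0
            mod.conv_v.weight.data[:] = 0.0
    fused = model(x).data
    assert np.abs(fused - ref).max() <= 1e-4


# -- FPN pathways -----------------------------------------------------------
def test_fpn_bottom_up_pyramid_sizes():
    model = _model("fpn_la")
    x = Tensor(np.random.default_rng(0).standard_normal((1, 1, 128, 128)).astype(np.float32))
    model.eval()
    feats = model.bottom_up(x)
    assert feats.f2.shape == (1, 64, 32, 32)    # 1/4
    assert feats.f3.shape == (1, 128, 16, 16)   # 1/8
    assert feats.f4.shape == (1, 256, 8, 8)     # 1/16
    assert feats.f5.shape == (1, 512, 4, 4)     # 1/32
    assert ResNet34BottomUp.STAGE_WIDTHS == (64, 128, 256, 512)
    assert ResNet34BottomUp.STAGE_BLOCKS == (3, 4, 6, 3)
    # F1 is never part of the pyramid
    assert set(feats.__dataclass_fields__) == {"f2", "f3", "f4", "f5"}


def test_fpn_top_down_shapes_and_lateral_ablation():
    model = _model("fpn_la").eval()
    x = Tensor(np.random.default_rng(3).standard_normal((1, 1, 64, 64)).astype(np.float32))
    feats = model.bottom_up(x)
    p = model.top_down(feats)
    for pi, fi in zip(p, (feats.f2, feats.f3, feats.f4, feats.f5)):
        assert pi.shape[2:] == fi.shape[2:]
        assert pi.shape[1] == 64
    # with lateral 1x1 weights zeroed below the top, P maps carry only F5
    for lat in model.top_down.lateral[:3]:
        lat.weight.data[:] = 0.0
        lat.bias.data[:] = 0.0
    p_zeroed = model.top_down(feats)
    other = model.bottom_up(Tensor(
        np.random.default_rng(4).standard_normal((1, 1, 64, 64)).astype(np.float32)))
    p_other = model.top_down(
        type(feats)(other.f2, other.f3, other.f4, feats.f5))
    np.testing.assert_allclose(p_zeroed[0].data, p_other[0].data, atol=1e-5)


def test_fpn_concatenated_pyramid_width_is_256():
    model = _model("fpn_la")
    assert model.aggregation.embed == 256


def test_fpn_parameter_count_independent_of_input_size(batch):
    model = _model("fpn_la").eval()
    n0 = model.n_parameters()
    model(Tensor(batch[0]))
    model(Tensor(np.zeros((1, 1, 96, 96), dtype=np.float32)))
    assert model.n_parameters() == n0


# -- checkpointing ----------------------------------------------------------
def test_checkpoint_round_trip(tmp_path, batch):
    cfg = ModelConfig(architecture="msunet", seed=5,
                      activation=ActivationSpec("leakyrelu", {"slope": 0.02}))
    model = build_model(cfg).eval()
    ref = model(Tensor(batch[0])).data
    save_checkpoint(model, cfg, tmp_path / "m.npz")
    loaded, cfg2 = load_checkpoint(tmp_path / "m.npz")
    loaded.eval()
    np.testing.assert_array_equal(loaded(Tensor(batch[0])).data, ref)
    assert cfg2.activation.params["slope"] == 0.02


def test_model_config_validation():
    with pytest.raises(ValueError, match="architecture"):
        ModelConfig(architecture="transformer")
    with pytest.raises(ValueError, match="levels"):
        ModelConfig(levels=2)
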