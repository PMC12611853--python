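"""Softmax attention oracle, linear attention and pyramid aggregation."""

import numpy as np
import pytest

from noduleseg.attention import (AttentionAggregation, AttentionInput,
                                 AttentionMatrices, linear_attention,
                                 project_qkv, softmax_attention)
from noduleseg.autograd import Tensor


def random_matrices(rng, m, dk, dv):
    return AttentionMatrices(rng.standard_normal((m, dk)),
                             rng.standard_normal((m, dk)),
                             rng.standard_normal((m, dv)))


def double_sum_linear_attention(mm: AttentionMatrices) -> np.ndarray:
    """O(M^2) per-query oracle: out_x = sum_y (1+qh.kh) v_y / sum_y (1+qh.kh)."""
    qh = mm.Q / np.linalg.norm(mm.Q, axis=1, keepdims=True)
    kh = mm.K / np.linalg.norm(mm.K, axis=1, keepdims=True)
    out = np.zeros((mm.Q.shape[0], mm.V.shape[1]))
    for x in range(mm.Q.shape[0]):
        num = np.zeros(mm.V.shape[1])
        den = 0.0
        for y in range(mm.K.shape[0]):
            wxy = 1.0 + qh[x] @ kh[y]
            num += wxy * mm.V[y]
            den += wxy
        out[x] = num / den
    return out


# -- projections -----------------------------------------------------------
def test_project_qkv_identity_and_zero(rng):
    i = rng.standard_normal((4, 3))
    eye = np.eye(3)
    m = project_qkv(AttentionInput(i, eye, eye, eye))
    np.testing.assert_allclose(m.Q, i)
    np.testing.assert_allclose(m.K, i)
    np.testing.assert_allclose(m.V, i)
    m0 = project_qkv(AttentionInput(i, eye, eye, np.zeros((3, 2))))
    np.testing.assert_allclose(m0.V, 0.0)


def test_project_qkv_against_triple_loop(rng):
    i = rng.standard_normal((3, 2))
    wq = np.array([[0.5, -1.0, 2.0], [1.5, 0.25, -0.5]])
    m = project_qkv(AttentionInput(i, wq, wq.copy(), wq.copy()))
    ref = np.zeros((3, 3))
    for r in range(3):
        for c in range(3):
            for k in range(2):
                ref[r, c] += i[r, k] * wq[k, c]
    np.testing.assert_allclose(m.Q, ref, atol=1e-12)


def test_project_qkv_dimension_checks(rng):
    i = rng.standard_normal((4, 3))
    with pytest.raises(ValueError, match="same width"):
        AttentionInput(i, np.zeros((3, 2)), np.zeros((3, 4)), np.zeros((3, 2)))
    with pytest.raises(ValueError, match="input rows"):
        AttentionInput(i, np.zeros((2, 2)), np.zeros((3, 2)), np.zeros((3, 2)))


# -- softmax attention ------------------------------------------------------
def test_softmax_attention_single_row_and_uniform(rng):
    m1 = random_matrices(rng, 1, 4, 3)
    np.testing.assert_allclose(softmax_attention(m1), m1.V, atol=1e-12)
    m = random_matrices(rng, 6, 4, 3)
    m.K[:] = m.K[0]  # identical keys -> uniform weights
    np.testing.assert_allclose(softmax_attention(m),
                               np.tile(m.V.mean(axis=0), (6, 1)), atol=1e-10)


def test_softmax_attention_matches_scipy(rng):
    from scipy.special import softmax as scipy_softmax

    m = random_matrices(rng, 12, 5, 4)
    ref = scipy_softmax(m.Q @ m.K.T, axis=1) @ m.V
    np.testing.assert_allclose(softmax_attention(m), ref, atol=1e-10)


# -- linear attention -------------------------------------------------------
def test_linear_attention_single_row_exact(rng):
    m1 = random_matrices(rng, 1, 4, 3)
    np.testing.assert_allclose(linear_attention(m1), m1.V, rtol=1e-5)


@pytest.mark.parametrize("seed", range(20))
def test_linear_attention_equals_double_sum_oracle(seed):
    rng = np.random.default_rng(seed)
    m = random_matrices(rng, int(rng.integers(2, 65)),
                        int(rng.integers(1, 17)), int(rng.integers(1, 17)))
    fast = linear_attention(m)
    slow = double_sum_linear_attention(m)
    assert np.abs(fast - slow).max() <= 1e-6


def test_implicit_weights_nonnegative_and_normalized(rng):
    m = random_matrices(rng, 32, 8, 4)
    qh = m.Q / np.linalg.norm(m.Q, axis=1, keepdims=True)
    kh = m.K / np.linalg.norm(m.K, axis=1, keepdims=True)
    w = (1.0 + qh @ kh.T) / (32 + qh @ kh.sum(axis=0))[:, None]
    assert (w >= -1e-12).all()          # Cauchy-Schwarz: qh.kh >= -1
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)


def test_linear_attention_zero_row_rejected(rng):
    m = random_matrices(rng, 4, 3, 2)
    m.Q[2] = 0.0
    with pytest.raises(ValueError, match="query row 2"):
        linear_attention(m)


def test_small_scale_limit(rng):
    """As s -> 0 softmax attention flattens to the column-mean of V, while
    linear attention over L2-normalized rows is exactly scale-invariant."""
    m = random_matrices(rng, 16, 6, 3)
    vbar = m.V.mean(axis=0)
    base = linear_attention(m)
    prev_gap = None
    for s in (1.0, 0.3, 0.1, 0.03, 0.01):
        ms = AttentionMatrices(s * m.Q, s * m.K, m.V)
        gap = np.abs(softmax_attention(ms) - vbar).max()
        if prev_gap is not None:
            assert gap <= prev_gap + 1e-9
        prev_gap = gap
        np.testing.assert_allclose(linear_attention(ms), base, atol=1e-9)
    assert prev_gap < 0.05 * np.abs(softmax_attention(m) - vbar).max()


def test_permutation_equivariance(rng):
    m = random_matrices(rng, 10, 4, 3)
    perm = np.random.default_rng(0).permutation(10)
    out = linear_attention(m)
    out_qperm = linear_attention(AttentionMatrices(m.Q[perm], m.K, m.V))
    np.testing.assert_allclose(out_qperm, out[perm], atol=1e-10)
    out_kvperm = linear_attention(AttentionMatrices(m.Q, m.K[perm], m.V[perm]))
    np.testing.assert_allclose(out_kvperm, out, atol=1e-10)


# -- aggregation module -----------------------------------------------------
def _pyramid(rng, b=1, d=8, hw=8):
    shapes = [(b, d, hw, hw), (b, d, hw // 2, hw // 2),
              (b, d, hw // 4, hw // 4), (b, d, hw // 8, hw // 8)]
    return [Tensor(rng.standard_normal(s).astype(np.float32)) for s in shapes]


def test_aggregation_contract_and_residual(rng):
    agg = AttentionAggregation(pyramid_width=8, rng=np.random.default_rng(0))
    p2, p3, p4, p5 = _pyramid(rng)
    out = agg(p2, p3, p4, p5)
    assert out.shape == (1, 32, 8, 8)
    # zero value projection -> refinement vanishes -> pure residual
    agg.proj_v.weight.data[:] = 0.0
    agg.proj_v.bias.data[:] = 0.0
    out0 = agg(p2, p3, p4, p5)
    from noduleseg.autograd import concatenate, functional as F
    cat = concatenate([p2, F.upsample_nearest(p3, 2), F.upsample_nearest(p4, 4),
                       F.upsample_nearest(p5, 8)], axis=1)
    np.testing.assert_allclose(out0.data, cat.data, atol=1e-5)


def test_aggregation_default_embedding_is_256():
    agg = AttentionAggregation(pyramid_width=64, rng=np.random.default_rng(0))
    assert agg.embed == 256


def test_aggregation_batch_mismatch_rejected(rng):
    agg = AttentionAggregation(pyramid_width=8, rng=np.random.default_rng(0))
    p2, p3, p4, p5 = _pyramid(rng)
    bad = Tensor(np.zeros((2,) + p3.shape[1:], dtype=np.float32))
    with pytest.raises(ValueError, match="batch"):
        agg(p2, bad, p4, p5)


def test_aggregation_matches_numpy_linear_attention(rng):
    """The trainable module reproduces the standalone math on its own QKV."""
    agg = AttentionAggregation(pyramid_width=4, rng=np.random.default_rng(1))
    p2, p3, p4, p5 = _pyramid(rng, d=4, hw=8)
    out = agg(p2, p3, p4, p5)
    from noduleseg.autograd import concatenate, functional as F
    cat = concatenate([p2, F.upsample_nearest(p3, 2), F.upsample_nearest(p4, 4),
                       F.upsample_nearest(p5, 8)], axis=1)
    fused = agg.fuse(cat)
    def flat(conv):
        return conv(fused).data[0].reshape(16, 64).T
    m = AttentionMatrices(flat(agg.proj_q), flat(agg.proj_k), flat(agg.proj_v))
    refined = linear_attention(m).T.reshape(16, 8, 8)
    np.testing.assert_allclose(out.data[0], cat.data[0] + refined,
                               rtol=1e-3, atol=1e-4)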