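"""Dot-product attention and its O(M) linear approximation.

The reference mechanism weights value rows by a row-softmax over query-key
similarities, which costs O(M^2) time and memory for M spatial positions.
Replacing exp(q.k) with its first-order Taylor expansion 1 + q.k — applied to
L2-normalized queries and keys so that q.k >= -1 keeps the implicit weights
non-negative — lets the key/value summaries

    S = sum_y khat_y vhat_y^T      and      z = sum_y khat_y

be computed once and reused for every query:

    out_x = (sum_y v_y + qhat_x^T S) / (M + qhat_x^T z)

which is linear in M.  The numpy functions here are the standalone math API;
:class:`AttentionAggregation` is the trainable module that applies the same
formula to concatenated feature-pyramid maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concatenate
from .autograd import functional as F
from .autograd.nn import Conv2d, Module


@dataclass
class AttentionInput:
    """Flattened spatial features I (M x D_i) with projection matrices."""

    I: np.ndarray
    W_q: np.ndarray
    W_k: np.ndarray
    W_v: np.ndarray

    def __post_init__(self):
        self.I = np.asarray(self.I, dtype=float)
        self.W_q = np.asarray(self.W_q, dtype=float)
        self.W_k = np.asarray(self.W_k, dtype=float)
        self.W_v = np.asarray(self.W_v, dtype=float)
        d_i = self.I.shape[1]
        for name, w in (("W_q", self.W_q), ("W_k", self.W_k), ("W_v", self.W_v)):
            if w.shape[0] != d_i:
                raise ValueError(
                    f"{name} has {w.shape[0]} input rows, expected D_i={d_i}"
                )
        if self.W_q.shape[1] != self.W_k.shape[1]:
            raise ValueError("query and key projections must have the same width")


@dataclass
class AttentionMatrices:
    Q: np.ndarray
    K: np.ndarray
    V: np.ndarray

    def __post_init__(self):
        if not (self.Q.shape[0] == self.K.shape[0] == self.V.shape[0]):
            raise ValueError("Q, K and V must have the same number of rows")
        if self.Q.shape[1] != self.K.shape[1]:
            raise ValueError("Q and K must have the same number of columns")


def project_qkv(inp: AttentionInput) -> AttentionMatrices:
    """Q = I W_q, K = I W_k, V = I W_v."""
    return AttentionMatrices(inp.I @ inp.W_q, inp.I @ inp.W_k, inp.I @ inp.W_v)


def softmax_attention(m: AttentionMatrices) -> np.ndarray:
    """Exact softmax dot-product attention; the O(M^2) reference."""
    scores = m.Q @ m.K.T
    scores -= scores.max(axis=1, keepdims=True)  # overflow guard
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    return w @ m.V


def _l2_rows(x: np.ndarray, what: str) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise ValueError(f"{what} row {bad[0]} is the zero vector; "
                         "L2 normalization is undefined")
    return x / norms[:, None]


def linear_attention(m: AttentionMatrices, eps: float = 1e-6) -> np.ndarray:
    """First-order-Taylor linear attention over L2-normalized Q and K.

    Never materializes an M x M array: only the D_k x D_v summary S and the
    D_k vector z are accumulated over keys.
    """
    mm = m.Q.shape[0]
    qh = _l2_rows(np.asarray(m.Q, dtype=float), "query")
    kh = _l2_rows(np.asarray(m.K, dtype=float), "key")
    v = np.asarray(m.V, dtype=float)
    s = kh.T @ v          # (D_k, D_v), computed once
    z = kh.sum(axis=0)    # (D_k,)
    denom = mm + qh @ z
    if np.any(denom <= eps):
        raise ValueError("attention denominator vanished "
                         "(all keys antipodal to a query)")
    num = v.sum(axis=0)[None, :] + qh @ s
    return num / (denom[:, None] + eps)


class AttentionAggregation(Module):
    """Aggregate pyramid maps P2..P5 with linear-attention refinement.

    P3..P5 are nearest-neighbour upsampled to P2's resolution and the four
    maps concatenated (4d channels; 256 for the default pyramid width d=64).
    A 1x1 convolution fuses the stack, single-head linear attention with
    1x1-convolution QKV projections refines the flattened positions, and the
    refined map is added residually to the concatenated features.
    """

    def __init__(self, pyramid_width: int = 64, eps: float = 1e-6,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.eps = eps
        self.embed = 4 * pyramid_width
        e = self.embed
        self.fuse = Conv2d(e, e, 1, rng=rng)
        self.proj_q = Conv2d(e, e, 1, rng=rng)
        self.proj_k = Conv2d(e, e, 1, rng=rng)
        self.proj_v = Conv2d(e, e, 1, rng=rng)

    def forward(self, p2: Tensor, p3: Tensor, p4: Tensor, p5: Tensor) -> Tensor:
        if not (p2.shape[0] == p3.shape[0] == p4.shape[0] == p5.shape[0]):
            raise ValueError("pyramid maps must share the batch dimension")
        b, _, h, w = p2.shape
        maps = [p2, F.upsample_nearest(p3, 2), F.upsample_nearest(p4, 4),
                F.upsample_nearest(p5, 8)]
        cat = concatenate(maps, axis=1)  # (B, 4d, H, W)
        fused = self.fuse(cat)
        e, m = self.embed, h * w

        def flat(t: Tensor) -> Tensor:
            return t.reshape(b, e, m).transpose(0, 2, 1)  # (B, M, E)

        q, k, v = flat(self.proj_q(fused)), flat(self.proj_k(fused)), flat(self.proj_v(fused))
        qn = ((q * q).sum(axis=2, keepdims=True) + self.eps).sqrt()
        kn = ((k * k).sum(axis=2, keepdims=True) + self.eps).sqrt()
        qh, kh = q / qn, k / kn
        s = kh.transpose(0, 2, 1) @ v                 # (B, E, E)
        z = kh.sum(axis=1, keepdims=True)             # (B, 1, E)
        vsum = v.sum(axis=1, keepdims=True)           # (B, 1, E)
        num = vsum + qh @ s                           # (B, M, E)
        den = (qh @ z.transpose(0, 2, 1)) + float(m) + self.eps  # (B, M, 1)
        refined = (num / den).transpose(0, 2, 1).reshape(b, e, h, w)
        return cat + refined
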