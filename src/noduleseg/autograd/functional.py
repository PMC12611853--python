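"""Convolution, pooling and resampling primitives for rank-4 feature maps.

All operations take (batch, channels, height, width) tensors.  Convolutions
use an im2col gather followed by one large matrix product; the column matrix
is re-gathered in the backward pass instead of stored, which keeps peak memory
proportional to the activations rather than to kernel-size-times-activations.
"""

from __future__ import annotations

import numpy as np

from .tensor import DTYPE, Tensor


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else tuple(v)


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, oh: int, ow: int) -> np.ndarray:
    b, c, _, _ = xp.shape
    cols = np.empty((b, c, kh, kw, oh, ow), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * oh : sh, j : j + sw * ow : sw]
    return cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride=1, padding=0) -> Tensor:
    """2-D cross-correlation; weight layout (out_ch, in_ch, kh, kw).

    Computed tap by tap in a channels-last layout: one (M, C_in) x
    (C_in, C_out) GEMM per kernel position, accumulated into the output.
    This keeps memory traffic at O(kh*kw) slice copies of the activation
    instead of materializing the kh*kw-times-larger im2col matrix.
    """
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    bsz, cin, hin, win = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    oh = (hin + 2 * ph - kh) // sh + 1
    ow = (win + 2 * pw - kw) // sw + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x.data
    xpt = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # (B, Hp, Wp, C)
    hp, wp = xpt.shape[1:3]
    m = bsz * oh * ow
    # On large maps a per-tap GEMM over the whole padded image (no gather
    # copy) is fastest; on small deep maps the padding overhead dominates and
    # gathering the true window per tap wins.
    use_full = sh == 1 and sw == 1 and m >= 2048

    def gather_taps(i, j):
        return xpt[:, i : i + sh * oh : sh, j : j + sw * ow : sw, :]

    out4 = np.zeros((bsz, oh, ow, cout), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            w_tap = w.data[:, :, i, j]
            if use_full:
                p_full = (xpt.reshape(-1, cin) @ w_tap.T).reshape(bsz, hp, wp, cout)
                out4 += p_full[:, i : i + oh, j : j + ow, :]
            else:
                xs = np.ascontiguousarray(gather_taps(i, j)).reshape(m, cin)
                out4 += (xs @ w_tap.T).reshape(bsz, oh, ow, cout)
    out = np.ascontiguousarray(out4.transpose(0, 3, 1, 2))
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(m, cout)
        need_x = x.requires_grad
        need_w = w.requires_grad
        gxpt = np.zeros_like(xpt) if need_x else None
        gw = np.zeros_like(w.data) if need_w else None
        for i in range(kh):
            for j in range(kw):
                if need_w:
                    xs = np.ascontiguousarray(gather_taps(i, j)).reshape(m, cin)
                    gw[:, :, i, j] = g2.T @ xs
                if need_x:
                    gxpt[:, i : i + sh * oh : sh, j : j + sw * ow : sw, :] += (
                        g2 @ w.data[:, :, i, j]
                    ).reshape(bsz, oh, ow, cin)
        if need_w:
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if need_x:
            gxp = np.ascontiguousarray(gxpt.transpose(0, 3, 1, 2))
            if ph or pw:
                gxp = gxp[:, :, ph : ph + hin, pw : pw + win]
            x._accum(gxp)

    return Tensor._result(out, parents, bw)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2) -> Tensor:
    """Transposed convolution restricted to kernel_size == stride.

    With non-overlapping kernels each input pixel expands into an independent
    stride-by-stride patch, which sidesteps checkerboard overlap entirely.
    Weight layout: (in_ch, out_ch, k, k).
    """
    k = stride
    bsz, cin, hin, win = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if (kh, kw) != (k, k):
        raise ValueError("conv_transpose2d: kernel size must equal stride")
    if cin != cin_w:
        raise ValueError(f"conv_transpose2d: input has {cin} channels, weight expects {cin_w}")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (B,H,W,CO,k,k)
    out = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
        bsz, cout, hin * k, win * k
    )
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gt = np.ascontiguousarray(
            g.reshape(bsz, cout, hin, k, win, k).transpose(0, 2, 4, 1, 3, 5)
        )  # (B,H,W,CO,k,k)
        if x.requires_grad:
            gx = np.tensordot(gt, w.data, axes=([3, 4, 5], [1, 2, 3]))  # (B,H,W,C)
            x._accum(np.ascontiguousarray(gx.transpose(0, 3, 1, 2)))
        if w.requires_grad:
            gw = np.tensordot(x.data, gt, axes=([0, 2, 3], [0, 1, 2]))
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._result(out, parents, bw)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    """Max pooling.  The common kernel==stride case uses a pure reshape."""
    stride = kernel if stride is None else stride
    bsz, c, h, w = x.data.shape
    if kernel == stride and padding == 0 and h % kernel == 0 and w % kernel == 0:
        k = kernel
        oh, ow = h // k, w // k
        xr = np.ascontiguousarray(
            x.data.reshape(bsz, c, oh, k, ow, k).transpose(0, 1, 2, 4, 3, 5)
        ).reshape(bsz, c, oh, ow, k * k)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

        def bw(g):
            if not x.requires_grad:
                return
            gxr = np.zeros((bsz, c, oh, ow, k * k), dtype=DTYPE)
            np.put_along_axis(gxr, idx[..., None], g[..., None], axis=-1)
            gx = (
                gxr.reshape(bsz, c, oh, ow, k, k)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(bsz, c, h, w)
            )
            x._accum(np.ascontiguousarray(gx))

        return Tensor._result(np.ascontiguousarray(out), (x,), bw)

    # general path (e.g. the 3x3/stride-2 stem pool)
    ph = pw = padding
    oh = (h + 2 * ph - kernel) // stride + 1
    ow = (w + 2 * pw - kernel) // stride + 1
    neg = np.finfo(DTYPE).min
    xp = np.full((bsz, c, h + 2 * ph, w + 2 * pw), neg, dtype=DTYPE)
    xp[:, :, ph : ph + h, pw : pw + w] = x.data
    cols = _im2col(xp, kernel, kernel, stride, stride, oh, ow)
    cols = cols.reshape(bsz, c, kernel * kernel, oh, ow)
    idx = cols.argmax(axis=2)
    out = np.take_along_axis(cols, idx[:, :, None], axis=2)[:, :, 0]

    def bw_general(g):
        if not x.requires_grad:
            return
        gcols = np.zeros((bsz, c, kernel * kernel, oh, ow), dtype=DTYPE)
        np.put_along_axis(gcols, idx[:, :, None], g[:, :, None], axis=2)
        gcols = gcols.reshape(bsz, c, kernel, kernel, oh, ow)
        gxp = np.zeros_like(xp)
        for i in range(kernel):
            for j in range(kernel):
                gxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += gcols[
                    :, :, i, j
                ]
        x._accum(gxp[:, :, ph : ph + h, pw : pw + w])

    return Tensor._result(np.ascontiguousarray(out), (x,), bw_general)


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Fused training-mode batch normalization over (batch, H, W).

    Returns ``(normalized, batch_mean, batch_var)``; the caller updates its
    running averages from the returned per-channel statistics.
    """
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gvec = gamma.data.reshape(1, -1, 1, 1)
    out = gvec * xhat + beta.data.reshape(1, -1, 1, 1)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gsum = g.sum(axis=axes, keepdims=True)
            gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
            gx = (gvec * inv_std) * (g - gsum / n - xhat * (gx_sum / n))
            x._accum(gx.astype(DTYPE))

    res = Tensor._result(out.astype(DTYPE), (x, gamma, beta), bw)
    return res, mu.reshape(-1), var.reshape(-1)


def avg_pool_global(x: Tensor, keepdims: bool = True) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=keepdims)


def max_pool_global(x: Tensor, keepdims: bool = True) -> Tensor:
    return x.max(axis=(2, 3), keepdims=keepdims)


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    bsz, c, h, w = x.data.shape
    data = np.repeat(np.repeat(x.data, factor, axis=2), factor, axis=3)

    def bw(g):
        if x.requires_grad:
            x._accum(
                g.reshape(bsz, c, h, factor, w, factor).sum(axis=(3, 5))
            )

    return Tensor._result(data, (x,), bw)


def _linear_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Row-stochastic interpolation matrix (align_corners=False convention)."""
    m = np.zeros((out_size, in_size), dtype=DTYPE)
    if in_size == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    src = np.clip(src, 0.0, in_size - 1.0)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = (src - lo).astype(DTYPE)
    m[np.arange(out_size), lo] += 1.0 - frac
    m[np.arange(out_size), hi] += frac
    return m


def upsample_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    _, _, h, w = x.data.shape
    oh, ow = out_hw
    a = _linear_matrix(oh, h)
    bm = _linear_matrix(ow, w)
    data = np.einsum("bchw,Hh,Ww->bcHW", x.data, a, bm, optimize=True).astype(DTYPE)

    def bw(g):
        if x.requires_grad:
            x._accum(
                np.einsum("bcHW,Hh,Ww->bchw", g, a, bm, optimize=True).astype(DTYPE)
            )

    return Tensor._result(data, (x,), bw)
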