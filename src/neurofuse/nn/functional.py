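"""Differentiable operations on 5-axis volumes (B, C, D, H, W).

conv3d is column-built im2col + BLAS: each (channel, kernel-offset) pair is
one strided-but-regular copy into a transposed patch matrix, followed by a
single GEMM.  Patch matrices live in a small reusable scratch arena —
re-allocating hundreds of MB per call costs more in page faults than the
copies themselves — and are chunked along output depth so peak scratch stays
within a fixed budget even for full-resolution (18x512x512) inputs.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

# cap on the im2col patch-matrix size (elements) per chunk
_IM2COL_BUDGET = 64 * 1024 * 1024

_ARENA: dict = {}


def _scratch(tag: str, shape, dtype) -> np.ndarray:
    """Reusable scratch array; tags keep concurrently-live buffers apart."""
    n = int(np.prod(shape))
    key = (tag, np.dtype(dtype))
    buf = _ARENA.get(key)
    if buf is None or buf.size < n:
        buf = np.empty(n, dtype)
        _ARENA[key] = buf
    return buf[:n].reshape(shape)


def _triple(v):
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3-tuple, got {v}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def conv_out_size(n: int, k: int, s: int, p: int) -> int:
    """Standard convolution output-size arithmetic along one axis."""
    out = (n + 2 * p - k) // s + 1
    if out < 1:
        raise ValueError(f"conv collapses axis of size {n} (k={k}, s={s}, p={p})")
    return out


def _windows(xp, kernel, stride):
    kd, kh, kw = kernel
    sd, sh, sw = stride
    v = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    return v[:, :, ::sd, ::sh, ::sw]  # (B, C, Do, Ho, Wo, kd, kh, kw)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0) -> Tensor:
    """3D cross-correlation. x (B,C,D,H,W), w (O,C,kd,kh,kw), b (O,).

    Internally the input is held channels-last so patch extraction reads
    contiguous C-runs; patches are (rows, kd*kh*kw*C) and both the forward
    pass and the weight gradient are single BLAS matmuls per depth chunk.
    """
    stride, padding = _triple(stride), _triple(padding)
    B, C, D, H, W = x.shape
    O, Cw, kd, kh, kw = w.shape
    if C != Cw:
        raise ValueError(f"conv3d channel mismatch: input {C}, weight {Cw}")
    sd, sh, sw = stride
    pd, ph, pw = padding
    Do = conv_out_size(D, kd, sd, pd)
    Ho = conv_out_size(H, kh, sh, ph)
    Wo = conv_out_size(W, kw, sw, pw)
    nk = kd * kh * kw

    dtype = x.data.dtype
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    ck = C * nk
    wmat = w.data.reshape(O, ck)  # column order: channel-major, offset-minor
    offsets = [(i, j, k) for i in range(kd) for j in range(kh) for k in range(kw)]
    chunk = max(1, _IM2COL_BUDGET // max(1, ck * Ho * Wo * B))

    def fill_patch(pT, d0, dd):
        """pT (ck, B*dd*Ho*Wo): one strided copy per (channel, offset)."""
        col = 0
        for c in range(C):
            for i, j, k in offsets:
                src = xp[:, c, i + d0 * sd:i + (d0 + dd) * sd:sd,
                         j:j + Ho * sh:sh, k:k + Wo * sw:sw]
                np.copyto(pT[col].reshape(B, dd, Ho, Wo), src)
                col += 1

    out = np.empty((B, O, Do, Ho, Wo), dtype=dtype)
    for d0 in range(0, Do, chunk):
        dd = min(Do, d0 + chunk) - d0
        rows = B * dd * Ho * Wo
        pT = _scratch("conv_patch", (ck, rows), dtype)
        fill_patch(pT, d0, dd)
        oT = _scratch("conv_out", (O, rows), dtype)
        np.matmul(wmat, pT, out=oT)
        out[:, :, d0:d0 + dd] = oT.reshape(O, B, dd, Ho, Wo).transpose(1, 0, 2, 3, 4)
    if b is not None:
        out += b.data.reshape(1, O, 1, 1, 1)

    rg = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)

    def bwd(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        need_dx = x.requires_grad
        dxp = np.zeros_like(xp) if need_dx else None
        dwmat = np.zeros((O, ck), dtype=w.data.dtype) if w.requires_grad else None
        for d0 in range(0, Do, chunk):
            dd = min(Do, d0 + chunk) - d0
            rows = B * dd * Ho * Wo
            gT = _scratch("conv_gout", (O, rows), dtype)
            np.copyto(gT.reshape(O, B, dd, Ho, Wo),
                      g[:, :, d0:d0 + dd].transpose(1, 0, 2, 3, 4))
            if dwmat is not None:
                pT = _scratch("conv_patch", (ck, rows), dtype)
                fill_patch(pT, d0, dd)
                dwmat += gT @ pT.T
            if need_dx:
                dpT = _scratch("conv_dpatch", (ck, rows), dtype)
                np.matmul(wmat.T, gT, out=dpT)
                col = 0
                for c in range(C):
                    for i, j, k in offsets:
                        dst = dxp[:, c, i + d0 * sd:i + (d0 + dd) * sd:sd,
                                  j:j + Ho * sh:sh, k:k + Wo * sw:sw]
                        dst += dpT[col].reshape(B, dd, Ho, Wo)
                        col += 1
        if dwmat is not None:
            w._accum(dwmat.reshape(w.data.shape))
        if need_dx:
            x._accum(np.ascontiguousarray(
                dxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W]))

    return Tensor._make(out, (x, w) + (() if b is None else (b,)), bwd, rg)


def max_pool3d(x: Tensor, kernel, stride, padding) -> Tensor:
    kernel, stride, padding = _triple(kernel), _triple(stride), _triple(padding)
    B, C, D, H, W = x.shape
    kd, kh, kw = kernel
    sd, sh, sw = stride
    pd, ph, pw = padding
    Do = conv_out_size(D, kd, sd, pd)
    Ho = conv_out_size(H, kh, sh, ph)
    Wo = conv_out_size(W, kw, sw, pw)
    neg = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else None
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)),
                constant_values=neg)
    win = _windows(xp, kernel, stride).reshape(B, C, Do, Ho, Wo, kd * kh * kw)
    arg = win.argmax(axis=-1)
    data = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxp = np.zeros_like(xp)
        ki, kj, kk = np.unravel_index(arg, (kd, kh, kw))
        bi, ci, di, hi, wi = np.indices(arg.shape, sparse=True)
        np.add.at(dxp, (bi, ci, di * sd + ki, hi * sh + kj, wi * sw + kk), g)
        x._accum(dxp[:, :, pd:pd + D, ph:ph + H, pw:pw + W])

    return Tensor._make(data, (x,), bwd, x.requires_grad)


# ----------------------------------------------------------- pixel (un)shuffle
def pixel_unshuffle_array(a: np.ndarray, r: int) -> np.ndarray:
    """Space-to-depth on (B,C,D,H,W): r x r spatial blocks become r^2 channels.

    out[b, c*r^2 + dh*r + dw, d, i, j] = a[b, c, d, i*r + dh, j*r + dw]
    """
    B, C, D, H, W = a.shape
    if H % r or W % r:
        raise ValueError(f"H={H}, W={W} not divisible by r={r}")
    v = a.reshape(B, C, D, H // r, r, W // r, r)
    return np.ascontiguousarray(v.transpose(0, 1, 4, 6, 2, 3, 5)).reshape(
        B, C * r * r, D, H // r, W // r)


def pixel_shuffle_array(a: np.ndarray, r: int) -> np.ndarray:
    """Depth-to-space inverse of :func:`pixel_unshuffle_array`."""
    B, C, D, H, W = a.shape
    if C % (r * r):
        raise ValueError(f"channels={C} not divisible by r^2={r * r}")
    c2 = C // (r * r)
    v = a.reshape(B, c2, r, r, D, H, W)
    return np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 6, 3)).reshape(
        B, c2, D, H * r, W * r)


def pixel_unshuffle(x: Tensor, r: int) -> Tensor:
    data = pixel_unshuffle_array(x.data, r)

    def bwd(g):
        x._accum(pixel_shuffle_array(g, r))

    return Tensor._make(data, (x,), bwd, x.requires_grad)


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    data = pixel_shuffle_array(x.data, r)

    def bwd(g):
        x._accum(pixel_unshuffle_array(g, r))

    return Tensor._make(data, (x,), bwd, x.requires_grad)


# --------------------------------------------------------------------- losses
def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; labels are integer class indices (B,)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    B = z.shape[0]
    nll = -(z[np.arange(B), labels] - np.log(ez.sum(axis=1)))
    data = np.asarray(nll.mean(), dtype=logits.data.dtype)

    def bwd(g):
        dz = p.copy()
        dz[np.arange(B), labels] -= 1.0
        logits._accum(dz * (g / B))

    return Tensor._make(data, (logits,), bwd, logits.requires_grad)
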