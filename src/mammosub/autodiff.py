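"""Minimal reverse-mode automatic differentiation on numpy arrays.

The registration network needs gradients through 2-D convolutions, a
bilinear spatial transformer, and the composite similarity/smoothness
loss.  This module provides exactly those primitives: a :class:`Tensor`
wrapping an ``ndarray`` with a recorded backward closure, and the ops the
U-Net and loss are built from.  Convolutions run as im2col + BLAS matmul;
the input gradient of a strided convolution is computed as a
zero-stuffed transposed convolution, so every heavy step is a matmul.

Conventions: activations are NCHW ``float32``; displacement fields are
``(N, 2, H, W)`` with channel 0 = row displacement, channel 1 = column
displacement, in pixels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "leaky_relu",
    "upsample_nearest",
    "concat_channels",
    "warp_bilinear",
    "masked_mse",
    "smoothness_penalty",
]


class Tensor:
    """An ndarray plus the tape entry needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        """Reverse-mode sweep from this tensor (default seed gradient 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # Small arithmetic surface — enough to combine loss terms.
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.float32(other))
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, scalar):
        s = float(scalar)
        out = Tensor(self.data * np.float32(s), parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * np.float32(s))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def item(self):
        return float(self.data)


def _unbroadcast(g, shape):
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


_BUFFERS: dict = {}


def _buffer(key, shape):
    """Reusable scratch array; shapes recur every training step, so
    reusing buffers avoids repeated large allocations and page faults."""
    buf = _BUFFERS.get(key)
    if buf is None or buf.shape != shape:
        buf = np.empty(shape, dtype=np.float32)
        _BUFFERS[key] = buf
    return buf


def _pad2d(x, pad):
    if pad == 0:
        return x
    n, c, h, w = x.shape
    out = _buffer(("pad", x.shape, pad), (n, c, h + 2 * pad, w + 2 * pad))
    out[:, :, :pad, :] = 0
    out[:, :, -pad:, :] = 0
    out[:, :, pad:-pad, :pad] = 0
    out[:, :, pad:-pad, -pad:] = 0
    out[:, :, pad : pad + h, pad : pad + w] = x
    return out


def _im2col(x, kh, kw, stride, pad, key=None):
    """Return (cols, out_h, out_w); cols is (N, C*kh*kw, out_h*out_w).

    Assembled kernel-tap by kernel-tap from strided slices of the padded
    input, which is far cheaper than transposing a 6-D sliding window.
    ``key`` identifies the call site: forward columns are kept alive
    until the backward pass, so each layer needs its own buffer.
    """
    n, c, h, w = x.shape
    xp = _pad2d(x, pad)
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    if key is None:
        cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=np.float32)
    else:
        cols = _buffer(key, (n, c, kh, kw, out_h, out_w))
    for p in range(kh):
        for q in range(kw):
            cols[:, :, p, q] = xp[
                :,
                :,
                p : p + (out_h - 1) * stride + 1 : stride,
                q : q + (out_w - 1) * stride + 1 : stride,
            ]
    return cols.reshape(n, c * kh * kw, out_h * out_w), out_h, out_w


def _corr2d_raw(x, w, stride, pad, key=None):
    """Plain cross-correlation on raw arrays; returns (y, cols)."""
    n = x.shape[0]
    o, c, kh, kw = w.shape
    cols, out_h, out_w = _im2col(x, kh, kw, stride, pad, key=key)
    y = np.matmul(w.reshape(o, c * kh * kw), cols)  # (N, O, P)
    return y.reshape(n, o, out_h, out_w), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 1) -> Tensor:
    """2-D cross-correlation with bias, NCHW layout."""
    n, c_in, h, wid = x.data.shape
    o, c_w, kh, kw = w.data.shape
    if c_w != c_in:
        raise ValueError(f"conv2d channel mismatch: input {c_in}, weight {c_w}")
    y, cols = _corr2d_raw(x.data, w.data, stride, pad, key=("fw", id(w)))
    y += b.data.reshape(1, o, 1, 1)
    out = Tensor(y, parents=(x, w, b))
    out_h, out_w = y.shape[2], y.shape[3]

    def bwd(g):
        gm = g.reshape(n, o, out_h * out_w)
        if w.requires_grad:
            dw = np.matmul(gm, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(o, c_in, kh, kw))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # dx = transposed conv: zero-stuff g by stride, full-pad, flip kernel.
            hs = (out_h - 1) * stride + 1
            ws = (out_w - 1) * stride + 1
            gs = _buffer(("bw-stuff", id(w)), (n, o, hs, ws))
            if stride > 1:
                gs[:] = 0
            gs[:, :, ::stride, ::stride] = g
            w_flip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
            )
            dxp, _ = _corr2d_raw(gs, w_flip, 1, kh - 1, key=("bw", id(w)))
            # dxp covers a (hs+kh-1, ws+kw-1) window of the padded input.
            hp, wp = h + 2 * pad, wid + 2 * pad
            dx_pad = np.zeros((n, c_in, hp, wp), dtype=np.float32)
            dx_pad[:, :, : dxp.shape[2], : dxp.shape[3]] = dxp
            x._accum(dx_pad[:, :, pad : pad + h, pad : pad + wid])

    out._backward = bwd
    return out


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    pos = x.data > 0
    out = Tensor(np.where(pos, x.data, np.float32(alpha) * x.data), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(np.where(pos, g, np.float32(alpha) * g))

    out._backward = bwd
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    y = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            n, c, h, w = x.data.shape
            x._accum(
                g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            )

    out._backward = bwd
    return out


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=1), parents=tuple(tensors)
    )
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def bwd(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=1)):
            if t.requires_grad:
                t._accum(gpart)

    out._backward = bwd
    return out


def _sample_coords(field_data, h, w):
    n = field_data.shape[0]
    gr, gc = np.meshgrid(
        np.arange(h, dtype=np.float32), np.arange(w, dtype=np.float32), indexing="ij"
    )
    r = gr[None] + field_data[:, 0]
    c = gc[None] + field_data[:, 1]
    rc = np.clip(r, 0.0, h - 1.0)
    cc = np.clip(c, 0.0, w - 1.0)
    r0 = np.minimum(np.floor(rc), h - 2).astype(np.int64) if h > 1 else np.zeros_like(rc, dtype=np.int64)
    c0 = np.minimum(np.floor(cc), w - 2).astype(np.int64) if w > 1 else np.zeros_like(cc, dtype=np.int64)
    fr = rc - r0
    fc = cc - c0
    # Clamp (border) sampling: no gradient flows to coordinates pushed
    # outside the image.
    in_r = (r > 0.0) & (r < h - 1.0)
    in_c = (c > 0.0) & (c < w - 1.0)
    return r0, c0, fr, fc, in_r, in_c


def warp_bilinear(image: Tensor, field: Tensor) -> Tensor:
    """Spatial transformer: bilinear sampling of ``image`` at grid + field.

    ``image`` is (N, C, H, W); ``field`` is (N, 2, H, W) in pixels of the
    output (fixed) frame.  Out-of-bounds sample positions clamp to the
    border.
    """
    if not np.all(np.isfinite(field.data)):
        raise ValueError("displacement field contains non-finite values")
    n, c, h, w = image.data.shape
    if field.data.shape != (n, 2, h, w):
        raise ValueError(
            f"field shape {field.data.shape} does not match image {image.data.shape}"
        )
    r0, c0, fr, fc, in_r, in_c = _sample_coords(field.data, h, w)
    r1, c1 = r0 + (1 if h > 1 else 0), c0 + (1 if w > 1 else 0)
    bidx = np.arange(n)[:, None, None]
    v00 = image.data[bidx, :, r0, c0].transpose(0, 3, 1, 2)
    v01 = image.data[bidx, :, r0, c1].transpose(0, 3, 1, 2)
    v10 = image.data[bidx, :, r1, c0].transpose(0, 3, 1, 2)
    v11 = image.data[bidx, :, r1, c1].transpose(0, 3, 1, 2)
    frb, fcb = fr[:, None], fc[:, None]
    w00 = (1 - frb) * (1 - fcb)
    w01 = (1 - frb) * fcb
    w10 = frb * (1 - fcb)
    w11 = frb * fcb
    y = w00 * v00 + w01 * v01 + w10 * v10 + w11 * v11
    out = Tensor(y, parents=(image, field))

    def bwd(g):
        if image.requires_grad:
            dimg = np.zeros_like(image.data)
            flat = dimg.reshape(n, c, h * w)
            ni = np.arange(n)[:, None, None, None]
            ci = np.arange(c)[None, :, None, None]
            for wgt, rr, cc in (
                (w00, r0, c0),
                (w01, r0, c1),
                (w10, r1, c0),
                (w11, r1, c1),
            ):
                idx = (rr * w + cc)[:, None, :, :]
                np.add.at(flat, (ni, ci, idx), g * wgt)
            image._accum(dimg)
        if field.requires_grad:
            d_fr = ((v10 - v00) * (1 - fcb) + (v11 - v01) * fcb) * g
            d_fc = ((v01 - v00) * (1 - frb) + (v11 - v10) * frb) * g
            gr = d_fr.sum(axis=1) * in_r
            gc = d_fc.sum(axis=1) * in_c
            field._accum(np.stack([gr, gc], axis=1))

    out._backward = bwd
    return out


def masked_mse(warped: Tensor, fixed: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared intensity difference over mask pixels, averaged over batch.

    ``fixed`` is (N, 1, H, W) or (1, H, W)-broadcastable; ``mask`` is boolean
    with the same spatial shape.  Raises on an empty mask.
    """
    fixed = np.asarray(fixed, dtype=np.float32)
    m = np.asarray(mask, dtype=np.float32)
    n = warped.data.shape[0]
    if m.ndim == 4:
        counts = m.sum(axis=(1, 2, 3))  # per-sample mask support
    else:
        counts = np.full(n, m.sum(), dtype=np.float32)
    if np.any(counts == 0):
        raise ValueError("mask is empty")
    diff = (warped.data - fixed) * m
    per_case = (diff * diff).sum(axis=(1, 2, 3)) / counts
    out = Tensor(np.float32(per_case.mean()), parents=(warped,))

    def bwd(g):
        if warped.requires_grad:
            scale = (g * 2.0 / (counts * n)).astype(np.float32)
            warped._accum(diff * scale[:, None, None, None])

    out._backward = bwd
    return out


def smoothness_penalty(field: Tensor) -> Tensor:
    """Mean squared forward-difference gradient of the field, per direction.

    For each spatial direction the squared forward differences of both
    displacement components are averaged over the valid positions and the
    two components; the two directional means are summed.  A field linear
    in the column index with slope ``c`` scores ``c**2 / 2``.
    """
    f = field.data
    n = f.shape[0]
    dr = f[:, :, 1:, :] - f[:, :, :-1, :]
    dc = f[:, :, :, 1:] - f[:, :, :, :-1]
    nr = np.float32(dr[0].size)
    nc = np.float32(dc[0].size)
    val = (dr * dr).sum() / (nr * n) + (dc * dc).sum() / (nc * n)
    out = Tensor(np.float32(val), parents=(field,))

    def bwd(g):
        if field.requires_grad:
            gf = np.zeros_like(f)
            gr = 2.0 * dr / (nr * n)
            gc = 2.0 * dc / (nc * n)
            gf[:, :, 1:, :] += gr
            gf[:, :, :-1, :] -= gr
            gf[:, :, :, 1:] += gc
            gf[:, :, :, :-1] -= gc
            field._accum(g * gf)

    out._backward = bwd
    return out
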