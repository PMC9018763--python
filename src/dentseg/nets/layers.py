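"""Minimal 3D CNN primitives with hand-derived backward passes.

All tensors are channel-first ``(C, D, H, W)`` float32.  Convolutions are
3x3x3, stride 1, same-padded, computed as an im2col matrix product so the
heavy lifting happens in BLAS.  These primitives exist because no deep
learning framework ships with this package; at the tiny desk-scale model
sizes used here they are fast enough for CPU training.
"""

from __future__ import annotations

import numpy as np

try:  # jitted direct-convolution kernels; pure-NumPy fallback below
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco


@njit(cache=True, fastmath=True)
def _conv3_fwd_kernel(xp, w, b, out):  # pragma: no cover - jitted
    cout, cin = w.shape[0], w.shape[1]
    d, h, ww = out.shape[1], out.shape[2], out.shape[3]
    for co in range(cout):
        for z in range(d):
            for y in range(h):
                row = out[co, z, y]
                for x in range(ww):
                    row[x] = b[co]
                for ci in range(cin):
                    for kz in range(3):
                        for ky in range(3):
                            xrow = xp[ci, z + kz, y + ky]
                            w0 = w[co, ci, kz, ky, 0]
                            w1 = w[co, ci, kz, ky, 1]
                            w2 = w[co, ci, kz, ky, 2]
                            for x in range(ww):
                                row[x] += w0 * xrow[x] + w1 * xrow[x + 1] + w2 * xrow[x + 2]


@njit(cache=True, fastmath=True)
def _conv3_dw_kernel(xp, g, dw, db):  # pragma: no cover - jitted
    # weight/bias gradients: one pass over (z, y) rows, all tap dot-products
    # run while the g and xp rows are cache-resident
    cout, cin = g.shape[0], xp.shape[0]
    d, h, ww = g.shape[1], g.shape[2], g.shape[3]
    dw[:] = 0.0
    db[:] = 0.0
    for z in range(d):
        for y in range(h):
            for co in range(cout):
                grow = g[co, z, y]
                s = 0.0
                for x in range(ww):
                    s += grow[x]
                db[co] += s
                for ci in range(cin):
                    for kz in range(3):
                        for ky in range(3):
                            xrow = xp[ci, z + kz, y + ky]
                            # three separate single-accumulator dots vectorize
                            s0 = 0.0
                            for x in range(ww):
                                s0 += grow[x] * xrow[x]
                            s1 = 0.0
                            for x in range(ww):
                                s1 += grow[x] * xrow[x + 1]
                            s2 = 0.0
                            for x in range(ww):
                                s2 += grow[x] * xrow[x + 2]
                            dw[co, ci, kz, ky, 0] += s0
                            dw[co, ci, kz, ky, 1] += s1
                            dw[co, ci, kz, ky, 2] += s2


def conv3d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, keep_cache: bool = True):
    """Same-padded 3x3x3 (or 1x1x1) convolution.

    x: (Cin, D, H, W); w: (Cout, Cin, k, k, k); b: (Cout,).
    Returns (out, cache) with out (Cout, D, H, W).

    The 3x3x3 path accumulates 27 shifted channel-mixing GEMMs instead of
    materializing an im2col matrix: at the few-channel widths used here the
    shifted slices stream through BLAS far faster than a strided gather, and
    the backward cache is just the padded input.
    """
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]
    d, h, ww = x.shape[1:]
    if k == 1:
        xf = x.reshape(cin, -1)
        out = (w.reshape(cout, cin) @ xf + b[:, None]).reshape(cout, d, h, ww)
        cache = (x, w, None) if keep_cache else None
        return out.astype(np.float32, copy=False), cache
    p = k // 2
    xp = np.pad(x.astype(np.float32, copy=False), ((0, 0), (p, p), (p, p), (p, p)))
    if HAVE_NUMBA:
        out = np.empty((cout, d, h, ww), dtype=np.float32)
        _conv3_fwd_kernel(xp, w, b, out)
        cache = (xp, w, x.shape) if keep_cache else None
        return out, cache
    n = d * h * ww
    out = np.broadcast_to(b[:, None], (cout, n)).copy()
    for kz in range(k):
        for ky in range(k):
            xs = xp[:, kz:kz + d, ky:ky + h, :]
            for kx in range(k):
                blk = np.ascontiguousarray(xs[..., kx:kx + ww]).reshape(cin, n)
                out += w[:, :, kz, ky, kx] @ blk
    cache = (xp, w, x.shape) if keep_cache else None
    return out.reshape(cout, d, h, ww), cache


def conv3d_backward(gout: np.ndarray, cache):
    """Gradients of conv3d_forward: returns (dx, dw, db)."""
    first, w, extra = cache
    cout = w.shape[0]
    k = w.shape[2]
    if k == 1:
        x = first
        cin, d, h, ww = x.shape
        g = gout.reshape(cout, -1)
        dw = (g @ x.reshape(cin, -1).T).reshape(w.shape)
        db = g.sum(axis=1)
        dx = (w.reshape(cout, cin).T @ g).reshape(x.shape)
        return dx.astype(np.float32, copy=False), dw, db
    xp, xshape = first, extra
    cin, d, h, ww = xshape
    p = k // 2
    if HAVE_NUMBA:
        g4 = np.ascontiguousarray(gout.reshape(cout, d, h, ww), dtype=np.float32)
        dw = np.empty_like(w)
        db = np.empty(cout, dtype=np.float32)
        _conv3_dw_kernel(xp, g4, dw, db)
        # input gradient = full correlation of g with the flipped, channel-
        # transposed kernel -> reuse the efficient forward kernel
        gp = np.pad(g4, ((0, 0), (p, p), (p, p), (p, p)))
        wt = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
        dx = np.empty((cin, d, h, ww), dtype=np.float32)
        _conv3_fwd_kernel(gp, wt, np.zeros(cin, dtype=np.float32), dx)
        return dx, dw, db
    n = d * h * ww
    g = np.ascontiguousarray(gout.reshape(cout, n))
    db = g.sum(axis=1)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for kz in range(k):
        for ky in range(k):
            xs = xp[:, kz:kz + d, ky:ky + h, :]
            ds = dxp[:, kz:kz + d, ky:ky + h, :]
            for kx in range(k):
                blk = np.ascontiguousarray(xs[..., kx:kx + ww]).reshape(cin, n)
                dw[:, :, kz, ky, kx] = g @ blk.T
                ds[..., kx:kx + ww] += (w[:, :, kz, ky, kx].T @ g).reshape(cin, d, h, ww)
    dx = dxp[:, p:p + d, p:p + h, p:p + ww]
    return np.ascontiguousarray(dx), dw, db


def relu_forward(x):
    out = np.maximum(x, 0.0)
    return out, (x > 0.0)


def relu_backward(gout, mask):
    return gout * mask


def avgpool2_forward(x):
    """2x downsampling by 2^3 block averaging; dims must be even."""
    c, d, h, w = x.shape
    out = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))
    return out.astype(np.float32, copy=False), x.shape


def avgpool2_backward(gout, xshape):
    g = np.repeat(np.repeat(np.repeat(gout, 2, axis=1), 2, axis=2), 2, axis=3)
    return (g / 8.0).astype(np.float32, copy=False)


def upsample2_forward(x):
    out = np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)
    return out, x.shape


def upsample2_backward(gout, xshape):
    c, d, h, w = xshape
    return gout.reshape(c, d, 2, h, 2, w, 2).sum(axis=(2, 4, 6)).astype(np.float32, copy=False)


def globalmaxpool_forward(x):
    """(C, D, H, W) -> (C,) max with argmax cache."""
    c = x.shape[0]
    flat = x.reshape(c, -1)
    idx = np.argmax(flat, axis=1)
    return flat[np.arange(c), idx].copy(), (idx, x.shape)


def globalmaxpool_backward(gout, cache):
    idx, shape = cache
    c = shape[0]
    dx = np.zeros((c, int(np.prod(shape[1:]))), dtype=np.float32)
    dx[np.arange(c), idx] = gout
    return dx.reshape(shape)


def linear_forward(x, w, b):
    return w @ x + b, x


def linear_backward(gout, x, w):
    return w.T @ gout, np.outer(gout, x), gout.copy()


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def softmax(x, axis=0):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
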