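"""Inner loops for the convolution layers.

numpy's im2col route spends most of its time gathering strided windows, so
the stride-1 'same' convolutions are written as explicit loops and jitted
with numba (pre-compiled lazily on first use). A pure-numpy fallback keeps
the package importable without numba; both paths compute identical values.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dep of the env
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco


@njit(cache=True)
def _conv1d_fwd_jit(xp, W, b, out):
    B, C, Lp = xp.shape
    O, _, k = W.shape
    L = Lp - k + 1
    for bi in range(B):
        for o in range(O):
            for l in range(L):
                out[bi, o, l] = b[o]
        for o in range(O):
            for c in range(C):
                for j in range(k):
                    w = W[o, c, j]
                    for l in range(L):
                        out[bi, o, l] += w * xp[bi, c, l + j]


@njit(cache=True)
def _conv1d_bwd_jit(xp, W, dout, dW, db, dxp):
    B, C, Lp = xp.shape
    O, _, k = W.shape
    L = Lp - k + 1
    for bi in range(B):
        for o in range(O):
            s = 0.0
            for l in range(L):
                s += dout[bi, o, l]
            db[o] += s
            for c in range(C):
                for j in range(k):
                    s = 0.0
                    w = W[o, c, j]
                    for l in range(L):
                        d = dout[bi, o, l]
                        s += d * xp[bi, c, l + j]
                        dxp[bi, c, l + j] += d * w
                    dW[o, c, j] += s


@njit(cache=True)
def _conv2d_fwd_jit(xp, W, b, out):
    B, C, Hp, Wp = xp.shape
    O = W.shape[0]
    k = W.shape[2]
    H = Hp - k + 1
    Wd = Wp - k + 1
    for bi in range(B):
        for o in range(O):
            for h in range(H):
                for w2 in range(Wd):
                    out[bi, o, h, w2] = b[o]
        for o in range(O):
            for c in range(C):
                for u in range(k):
                    for v in range(k):
                        wv = W[o, c, u, v]
                        for h in range(H):
                            for w2 in range(Wd):
                                out[bi, o, h, w2] += wv * xp[bi, c, h + u, w2 + v]


@njit(cache=True)
def _conv2d_bwd_jit(xp, W, dout, dW, db, dxp):
    B, C, Hp, Wp = xp.shape
    O = W.shape[0]
    k = W.shape[2]
    H = Hp - k + 1
    Wd = Wp - k + 1
    for bi in range(B):
        for o in range(O):
            s = 0.0
            for h in range(H):
                for w2 in range(Wd):
                    s += dout[bi, o, h, w2]
            db[o] += s
            for c in range(C):
                for u in range(k):
                    for v in range(k):
                        wv = W[o, c, u, v]
                        s = 0.0
                        for h in range(H):
                            for w2 in range(Wd):
                                d = dout[bi, o, h, w2]
                                s += d * xp[bi, c, h + u, w2 + v]
                                dxp[bi, c, h + u, w2 + v] += d * wv
                        dW[o, c, u, v] += s


# ---------------------------------------------------------------------------
# public wrappers (numpy fallback uses im2col + GEMM)


def conv1d_forward(xp: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    B, C, Lp = xp.shape
    O, _, k = W.shape
    L = Lp - k + 1
    if _HAVE_NUMBA:
        out = np.empty((B, O, L))
        _conv1d_fwd_jit(xp, W, b, out)
        return out
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    cols = win.transpose(0, 2, 1, 3).reshape(B * L, C * k)
    out = cols @ W.reshape(O, -1).T + b
    return out.reshape(B, L, O).transpose(0, 2, 1)


def conv1d_backward(xp, W, dout):
    B, C, Lp = xp.shape
    O, _, k = W.shape
    L = Lp - k + 1
    dW = np.zeros_like(W)
    db = np.zeros_like(np.zeros(O))
    dxp = np.zeros_like(xp)
    if _HAVE_NUMBA:
        _conv1d_bwd_jit(xp, W, dout, dW, db, dxp)
        return dW, db, dxp
    dmat = dout.transpose(0, 2, 1).reshape(B * L, O)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)
    cols = win.transpose(0, 2, 1, 3).reshape(B * L, C * k)
    dW[...] = (dmat.T @ cols).reshape(W.shape)
    db[...] = dmat.sum(axis=0)
    dcols = (dmat @ W.reshape(O, -1)).reshape(B, L, C, k)
    for j in range(k):
        dxp[:, :, j : j + L] += dcols[:, :, :, j].transpose(0, 2, 1)
    return dW, db, dxp


def conv2d_forward(xp: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    B, C, Hp, Wp = xp.shape
    O = W.shape[0]
    k = W.shape[2]
    H, Wd = Hp - k + 1, Wp - k + 1
    if _HAVE_NUMBA:
        out = np.empty((B, O, H, Wd))
        _conv2d_fwd_jit(xp, W, b, out)
        return out
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * k * k)
    out = cols @ W.reshape(O, -1).T + b
    return out.reshape(B, H, Wd, O).transpose(0, 3, 1, 2)


def conv2d_backward(xp, W, dout):
    B, C, Hp, Wp = xp.shape
    O = W.shape[0]
    k = W.shape[2]
    H, Wd = Hp - k + 1, Wp - k + 1
    dW = np.zeros_like(W)
    db = np.zeros(O)
    dxp = np.zeros_like(xp)
    if _HAVE_NUMBA:
        _conv2d_bwd_jit(xp, W, dout, dW, db, dxp)
        return dW, db, dxp
    dmat = dout.transpose(0, 2, 3, 1).reshape(B * H * Wd, O)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * Wd, C * k * k)
    dW[...] = (dmat.T @ cols).reshape(W.shape)
    db[...] = dmat.sum(axis=0)
    dcols = (dmat @ W.reshape(O, -1)).reshape(B, H, Wd, C, k, k)
    for u in range(k):
        for v in range(k):
            dxp[:, :, u : u + H, v : v + Wd] += dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
    return dW, db, dxp
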