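"""Numba JIT kernels for 3D convolution forward/backward passes.

Layout is channels-first ``(C, N, D, H, W)`` float32. Loops are ordered so
that one (channel, sample) spatial plane stays cache-resident while the
innermost contiguous axis vectorizes; with the small channel counts used by
the volumetric enhancer this outperforms im2col + GEMM by a wide margin
because it avoids the k^3-fold memory inflation of the patch matrix.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "conv3d_forward",
    "conv3d_backward_dx",
    "conv3d_backward_dw",
    "convT3d_forward",
    "convT3d_backward_dx",
    "convT3d_backward_dw",
    "scale_shift",
    "channel_sums",
    "affine_combine",
    "elu_forward",
    "elu_backward",
]


@njit(fastmath=True, cache=False)
def scale_shift(x, a, b, out):
    """out[c, i] = x[c, i] * a[c] + b[c] on channel-leading 2D views."""
    C, M = x.shape
    for c in range(C):
        ac, bc = a[c], b[c]
        xr, orow = x[c], out[c]
        for i in range(M):
            orow[i] = xr[i] * ac + bc


@njit(fastmath=True, cache=False)
def channel_sums(g, x, s1, s2):
    """Per-channel sums s1[c] = sum g, s2[c] = sum g * x (2D views)."""
    C, M = g.shape
    for c in range(C):
        gr, xr = g[c], x[c]
        a = np.float32(0.0)
        b = np.float32(0.0)
        for i in range(M):
            a += gr[i]
            b += gr[i] * xr[i]
        s1[c] = a
        s2[c] = b


@njit(fastmath=True, cache=False)
def affine_combine(g, x, A, B, C_, out):
    """out[c, i] = A[c] * g[c, i] + B[c] + C_[c] * x[c, i] (2D views)."""
    C, M = g.shape
    for c in range(C):
        ac, bc, cc = A[c], B[c], C_[c]
        gr, xr, orow = g[c], x[c], out[c]
        for i in range(M):
            orow[i] = ac * gr[i] + bc + cc * xr[i]


@njit(fastmath=True, cache=False)
def elu_forward(x, out):
    n = x.size
    xf = x.reshape(n)
    of = out.reshape(n)
    for i in range(n):
        v = xf[i]
        of[i] = v if v > 0 else np.expm1(v)


@njit(fastmath=True, cache=False)
def elu_backward(g, y, out):
    n = g.size
    gf = g.reshape(n)
    yf = y.reshape(n)
    of = out.reshape(n)
    for i in range(n):
        of[i] = gf[i] * (np.float32(1.0) if yf[i] > 0 else yf[i] + np.float32(1.0))


@njit(fastmath=True, cache=False)
def _conv3d_forward_s1(xp, W, out):
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    _, N, Do, Ho, Wo = out.shape
    for n in range(N):
        for co in range(cout):
            o = out[co, n]
            for ci in range(cin):
                xpl = xp[ci, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            w = W[co, ci, i, j, l]
                            for d in range(Do):
                                for h in range(Ho):
                                    xr = xpl[d + i, h + j]
                                    orow = o[d, h]
                                    for v in range(Wo):
                                        orow[v] += w * xr[l + v]


@njit(fastmath=True, cache=False)
def _conv3d_forward_strided(xp, W, out, s):
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    _, N, Do, Ho, Wo = out.shape
    for n in range(N):
        for co in range(cout):
            o = out[co, n]
            for ci in range(cin):
                xpl = xp[ci, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            w = W[co, ci, i, j, l]
                            for d in range(Do):
                                for h in range(Ho):
                                    xr = xpl[d * s + i, h * s + j]
                                    orow = o[d, h]
                                    for v in range(Wo):
                                        orow[v] += w * xr[l + v * s]


def conv3d_forward(xp, W, out, s):
    if s == 1:
        _conv3d_forward_s1(xp, W, out)
    else:
        _conv3d_forward_strided(xp, W, out, s)


@njit(fastmath=True, cache=False)
def _conv3d_backward_dx_s1(g, W, dxp):
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    _, N, Do, Ho, Wo = g.shape
    for n in range(N):
        for ci in range(cin):
            dxl = dxp[ci, n]
            for co in range(cout):
                gl = g[co, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            w = W[co, ci, i, j, l]
                            for d in range(Do):
                                for h in range(Ho):
                                    grow = gl[d, h]
                                    dxr = dxl[d + i, h + j]
                                    for v in range(Wo):
                                        dxr[l + v] += w * grow[v]


@njit(fastmath=True, cache=False)
def _conv3d_backward_dx_strided(g, W, dxp, s):
    cout, cin, k = W.shape[0], W.shape[1], W.shape[2]
    _, N, Do, Ho, Wo = g.shape
    for n in range(N):
        for ci in range(cin):
            dxl = dxp[ci, n]
            for co in range(cout):
                gl = g[co, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            w = W[co, ci, i, j, l]
                            for d in range(Do):
                                for h in range(Ho):
                                    grow = gl[d, h]
                                    dxr = dxl[d * s + i, h * s + j]
                                    for v in range(Wo):
                                        dxr[l + v * s] += w * grow[v]


def conv3d_backward_dx(g, W, dxp, s):
    if s == 1:
        _conv3d_backward_dx_s1(g, W, dxp)
    else:
        _conv3d_backward_dx_strided(g, W, dxp, s)


@njit(fastmath=True, cache=False)
def _conv3d_backward_dw_s1(g, xp, dW):
    # row-reuse ordering: each (g row, x row) pair is loaded once and feeds
    # all k kernel taps, keeping the reduction in L1 cache
    cout, cin, k = dW.shape[0], dW.shape[1], dW.shape[2]
    _, N, Do, Ho, Wo = g.shape
    for n in range(N):
        for co in range(cout):
            gl = g[co, n]
            for ci in range(cin):
                xpl = xp[ci, n]
                for d in range(Do):
                    for h in range(Ho):
                        grow = gl[d, h]
                        for i in range(k):
                            for j in range(k):
                                xr = xpl[d + i, h + j]
                                for l in range(k):
                                    acc = np.float32(0.0)
                                    for v in range(Wo):
                                        acc += grow[v] * xr[l + v]
                                    dW[co, ci, i, j, l] += acc


@njit(fastmath=True, cache=False)
def _conv3d_backward_dw_strided(g, xp, dW, s):
    cout, cin, k = dW.shape[0], dW.shape[1], dW.shape[2]
    _, N, Do, Ho, Wo = g.shape
    for n in range(N):
        for co in range(cout):
            gl = g[co, n]
            for ci in range(cin):
                xpl = xp[ci, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            acc = np.float32(0.0)
                            for d in range(Do):
                                for h in range(Ho):
                                    grow = gl[d, h]
                                    xr = xpl[d * s + i, h * s + j]
                                    for v in range(Wo):
                                        acc += grow[v] * xr[l + v * s]
                            dW[co, ci, i, j, l] += acc


def conv3d_backward_dw(g, xp, dW, s):
    if s == 1:
        _conv3d_backward_dw_s1(g, xp, dW)
    else:
        _conv3d_backward_dw_strided(g, xp, dW, s)


@njit(fastmath=True, cache=False)
def convT3d_forward(x, W, out):
    cin, cout, k = W.shape[0], W.shape[1], W.shape[2]
    _, N, D, H, Wd = x.shape
    for n in range(N):
        for co in range(cout):
            o = out[co, n]
            for ci in range(cin):
                xl = x[ci, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            w = W[ci, co, i, j, l]
                            for d in range(D):
                                for h in range(H):
                                    xr = xl[d, h]
                                    orow = o[d * k + i, h * k + j]
                                    for v in range(Wd):
                                        orow[l + v * k] += w * xr[v]


@njit(fastmath=True, cache=False)
def convT3d_backward_dx(g, W, dx):
    cin, cout, k = W.shape[0], W.shape[1], W.shape[2]
    _, N, D, H, Wd = dx.shape
    for n in range(N):
        for ci in range(cin):
            dxl = dx[ci, n]
            for co in range(cout):
                gl = g[co, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            w = W[ci, co, i, j, l]
                            for d in range(D):
                                for h in range(H):
                                    grow = gl[d * k + i, h * k + j]
                                    dxr = dxl[d, h]
                                    for v in range(Wd):
                                        dxr[v] += w * grow[l + v * k]


@njit(fastmath=True, cache=False)
def convT3d_backward_dw(g, x, dW):
    cin, cout, k = dW.shape[0], dW.shape[1], dW.shape[2]
    _, N, D, H, Wd = x.shape
    for n in range(N):
        for ci in range(cin):
            xl = x[ci, n]
            for co in range(cout):
                gl = g[co, n]
                for i in range(k):
                    for j in range(k):
                        for l in range(k):
                            acc = np.float32(0.0)
                            for d in range(D):
                                for h in range(H):
                                    xr = xl[d, h]
                                    grow = gl[d * k + i, h * k + j]
                                    for v in range(Wd):
                                        acc += xr[v] * grow[l + v * k]
                            dW[ci, co, i, j, l] += acc
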