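"""Numba-compiled convolution kernels (optional fast path for ``slenet.nn``).

Depthwise convolutions run in NCHW layout with the kernel window innermost;
batch-norm statistics/normalisation and the SiLU activation are fused
single-pass loops.  The NumPy implementations in ``slenet.nn`` remain the
reference; these kernels compute the same quantities and are exercised by
the same oracle and finite-difference tests through the public layer API.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by the layer tests
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # noqa: D103
        def wrap(f):
            return f

        return wrap


@njit(cache=True, fastmath=True)
def depthwise_fwd(xp, w, out, stride):
    """xp (B,C,Hp,Wp), w (C,K,K), out (B,C,Ho,Wo) accumulated in place."""
    b_sz, c_sz, ho, wo = out.shape
    k = w.shape[1]
    for b in range(b_sz):
        for c in range(c_sz):
            for oi in range(ho):
                ii = oi * stride
                for oj in range(wo):
                    jj = oj * stride
                    acc = 0.0
                    for di in range(k):
                        for dj in range(k):
                            acc += xp[b, c, ii + di, jj + dj] * w[c, di, dj]
                    out[b, c, oi, oj] = acc


@njit(cache=True, fastmath=True)
def depthwise_bwd(xp, w, g, dxp, dw, stride):
    """Gradients for depthwise_fwd; accumulates dxp and dw."""
    b_sz, c_sz, ho, wo = g.shape
    k = w.shape[1]
    for b in range(b_sz):
        for c in range(c_sz):
            for oi in range(ho):
                ii = oi * stride
                for oj in range(wo):
                    jj = oj * stride
                    gv = g[b, c, oi, oj]
                    for di in range(k):
                        for dj in range(k):
                            dw[c, di, dj] += xp[b, c, ii + di, jj + dj] * gv
                            dxp[b, c, ii + di, jj + dj] += w[c, di, dj] * gv


@njit(cache=True, fastmath=True)
def bn_stats(x):
    """Per-channel (sum, sum of squares) over (B, H, W) of an NCHW array."""
    b_sz, c_sz, h, w = x.shape
    s = np.zeros(c_sz, dtype=np.float64)
    ss = np.zeros(c_sz, dtype=np.float64)
    for b in range(b_sz):
        for c in range(c_sz):
            acc = 0.0
            acc2 = 0.0
            for i in range(h):
                for j in range(w):
                    v = x[b, c, i, j]
                    acc += v
                    acc2 += v * v
            s[c] += acc
            ss[c] += acc2
    return s, ss


@njit(cache=True, fastmath=True)
def bn_fwd(x, mean, invstd, gamma, beta, xhat, y):
    """Normalise and affine-transform in one pass; fills xhat and y."""
    b_sz, c_sz, h, w = x.shape
    for b in range(b_sz):
        for c in range(c_sz):
            mu = mean[c]
            isd = invstd[c]
            ga = gamma[c]
            be = beta[c]
            for i in range(h):
                for j in range(w):
                    xh = (x[b, c, i, j] - mu) * isd
                    xhat[b, c, i, j] = xh
                    y[b, c, i, j] = ga * xh + be


@njit(cache=True, fastmath=True)
def bn_bwd_reduce(g, xhat):
    """Per-channel (sum g, sum g*xhat)."""
    b_sz, c_sz, h, w = g.shape
    gs = np.zeros(c_sz, dtype=np.float64)
    gd = np.zeros(c_sz, dtype=np.float64)
    for b in range(b_sz):
        for c in range(c_sz):
            a1 = 0.0
            a2 = 0.0
            for i in range(h):
                for j in range(w):
                    gv = g[b, c, i, j]
                    a1 += gv
                    a2 += gv * xhat[b, c, i, j]
            gs[c] += a1
            gd[c] += a2
    return gs, gd


@njit(cache=True, fastmath=True)
def bn_bwd_apply(g, xhat, gamma, invstd, gsum, gdot, n, out):
    """out = gamma*invstd/n * (n*g - gsum - xhat*gdot)."""
    b_sz, c_sz, h, w = g.shape
    for b in range(b_sz):
        for c in range(c_sz):
            scale = gamma[c] * invstd[c] / n
            gs = gsum[c]
            gd = gdot[c]
            for i in range(h):
                for j in range(w):
                    out[b, c, i, j] = scale * (
                        n * g[b, c, i, j] - gs - xhat[b, c, i, j] * gd
                    )


@njit(cache=True, fastmath=True)
def silu_fwd(x, y, s):
    """y = x * sigmoid(x); also stores the sigmoid for the backward pass."""
    for i in range(x.size):
        v = x[i]
        if v < -30.0:
            sv = 0.0
        elif v > 30.0:
            sv = 1.0
        else:
            sv = 1.0 / (1.0 + np.exp(-v))
        s[i] = sv
        y[i] = v * sv


@njit(cache=True, fastmath=True)
def silu_bwd(x, s, g, out):
    """out = g * s * (1 + x * (1 - s)), all flat float32 views."""
    for i in range(x.size):
        sv = s[i]
        out[i] = g[i] * (sv * (1.0 + x[i] * (1.0 - sv)))
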