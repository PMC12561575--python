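"""Non-local self-attention over the spatial positions of a feature map.

The head feature map (C x H x W) is flattened to N = H*W position vectors
X (N x C).  Scaled dot-product attention

    Q = X Wq,  K = X Wk,  V = X Wv
    FA(Q, K, V) = softmax(Q K^T / sqrt(dk)) V

mixes information between every pair of positions (no positional encoding,
so the block is equivariant to spatial permutations).  The block output is
``x + reshape(FA(...) Wz)``: an output projection ``Wz`` (zero-initialised,
so the block is the identity at initialisation) plus a residual connection.
The softmax is computed row-wise over the key axis with max-subtraction, so
every attention row is a convex combination of the value rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn

__all__ = [
    "NonLocalParams",
    "attention_matrix",
    "scaled_attention",
    "nonlocal_block",
    "NonLocalBlock",
]


@dataclass
class NonLocalParams:
    channels: int
    dk: int
    Wq: np.ndarray = field(default=None)
    Wk: np.ndarray = field(default=None)
    Wv: np.ndarray = field(default=None)
    Wz: np.ndarray = field(default=None)  # dk x C output projection
    residual: bool = True

    def __post_init__(self):
        if self.dk <= 0:
            raise ValueError("dk must be positive")
        for name in ("Wq", "Wk", "Wv"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros((self.channels, self.dk)))
        if self.Wz is None:
            self.Wz = np.zeros((self.dk, self.channels))
        for name in ("Wq", "Wk", "Wv", "Wz"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, m)


def _validated(X):
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be N x C with N >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("X must be finite")
    return X


def attention_matrix(X, p: NonLocalParams):
    """The N x N row-stochastic matrix softmax(Q K^T / sqrt(dk))."""
    X = _validated(X)
    q, k = X @ p.Wq, X @ p.Wk
    return nn.softmax((q @ k.T) / math.sqrt(p.dk), axis=1)


def scaled_attention(X, p: NonLocalParams):
    """softmax(Q K^T / sqrt(dk)) V for X of shape (N, C); returns (N, dk)."""
    X = _validated(X)
    return attention_matrix(X, p) @ (X @ p.Wv)


def nonlocal_block(x, p: NonLocalParams):
    """Apply the block to one C x H x W feature map."""
    x = np.asarray(x, dtype=np.float64)
    c, h, w = x.shape
    X = x.reshape(c, h * w).T
    y = scaled_attention(X, p) @ p.Wz
    out = y.T.reshape(c, h, w)
    return x + out if p.residual else out


class NonLocalBlock(nn.Module):
    """Batched trainable non-local block (dk = C by default)."""

    def __init__(self, channels, dk=None, residual=True, rng=None):
        rng = rng or np.random.default_rng(0)
        dk = dk or channels
        self.channels, self.dk, self.residual = channels, dk, residual
        std = math.sqrt(1.0 / channels)
        self.Wq = nn.Parameter(rng.normal(0.0, std, (channels, dk)))
        self.Wk = nn.Parameter(rng.normal(0.0, std, (channels, dk)))
        self.Wv = nn.Parameter(rng.normal(0.0, std, (channels, dk)))
        # zero output projection: the block starts as the identity
        self.Wz = nn.Parameter(np.zeros((dk, channels)))

    def forward(self, x):
        b, c, h, w = x.shape
        X = x.reshape(b, c, h * w).transpose(0, 2, 1)  # (B, N, C)
        q = X @ self.Wq.data
        k = X @ self.Wk.data
        v = X @ self.Wv.data
        a = nn.softmax((q @ k.transpose(0, 2, 1)) / math.sqrt(self.dk), axis=2)
        y = a @ v
        z = y @ self.Wz.data
        self._cache = (X, q, k, v, a, y, (b, c, h, w))
        out = np.ascontiguousarray(z.transpose(0, 2, 1).reshape(b, c, h, w))
        return x + out if self.residual else out

    def backward(self, grad):
        X, q, k, v, a, y, (b, c, h, w) = self._cache
        dz = grad.reshape(b, c, h * w).transpose(0, 2, 1)  # (B, N, C)
        self.Wz.grad += np.einsum("bnd,bnc->dc", y, dz)
        dy = dz @ self.Wz.data.T
        da = dy @ v.transpose(0, 2, 1)
        dv = a.transpose(0, 2, 1) @ dy
        ds = a * (da - np.sum(da * a, axis=2, keepdims=True))
        ds /= math.sqrt(self.dk)
        dq = ds @ k
        dk_ = ds.transpose(0, 2, 1) @ q
        self.Wq.grad += np.einsum("bnc,bnd->cd", X, dq)
        self.Wk.grad += np.einsum("bnc,bnd->cd", X, dk_)
        self.Wv.grad += np.einsum("bnc,bnd->cd", X, dv)
        dX = dq @ self.Wq.data.T + dk_ @ self.Wk.data.T + dv @ self.Wv.data.T
        dx = np.ascontiguousarray(dX.transpose(0, 2, 1).reshape(b, c, h, w))
        return grad + dx if self.residual else dx

    def macs(self, h, w):
        n = h * w
        proj = 3 * n * self.channels * self.dk + n * self.dk * self.channels
        attn = 2 * n * n * self.dk
        return proj + attn, (h, w)
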