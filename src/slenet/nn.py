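"""Minimal NumPy neural-network engine: layers with explicit backward passes.

The package trains its convolutional classifier with hand-written
forward/backward passes on float32 NumPy arrays (NCHW layout).  Every layer
caches exactly what its backward pass needs; gradients accumulate into
``Parameter.grad``.  Correctness of each backward pass is pinned by
finite-difference checks in the test suite.

Conventions
-----------
* ``Module.training`` toggles batch-norm statistics and dropout.
* K x K convolutions are evaluated as a sum over the K^2 kernel offsets of
  channel-mixing matrix products, which keeps 1x1 convolutions (the bulk of
  the compute in an inverted-bottleneck network) on the BLAS fast path.
* MAC counting (``macs`` methods) covers convolution / linear / attention
  matrix products only; normalisation, activations and elementwise gating are
  excluded.  See the complexity-report documentation for the convention.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "SiLU",
    "Sigmoid",
    "Linear",
    "Dropout",
    "GlobalAvgPool",
    "AdamW",
    "softmax",
    "cross_entropy",
    "silu",
    "sigmoid",
]


def sigmoid(x):
    x = np.asarray(x)
    out = np.empty_like(x, dtype=np.float64 if x.dtype == np.float64 else np.float32)
    np.clip(x, -60.0, 60.0, out=out)
    np.negative(out, out=out)
    np.exp(out, out=out)
    out += 1.0
    np.reciprocal(out, out=out)
    return out


def silu(x):
    return x * sigmoid(x)


def softmax(z, axis=-1):
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


class Parameter:
    """A trainable array plus its gradient accumulator.

    ``decay`` marks whether decoupled weight decay applies (weight matrices
    yes; biases and batch-norm affine terms no).
    """

    def __init__(self, data, decay=True):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.decay = decay

    @property
    def size(self):
        return self.data.size


class Module:
    training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def modules(self):
        yield self
        for c in self._children():
            yield from c.modules()

    def parameters(self):
        params = []
        for m in self.modules():
            for v in m.__dict__.values():
                if isinstance(v, Parameter):
                    params.append(v)
        return params

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self):
        return int(sum(p.size for p in self.parameters()))

    def named_buffers(self):
        """Non-trainable state (e.g. batch-norm running statistics)."""
        for m in self.modules():
            for name in getattr(m, "buffer_names", ()):
                yield m, name

    def state_dict(self):
        state = [p.data.copy() for p in self.parameters()]
        state += [np.array(getattr(m, n), copy=True) for m, n in self.named_buffers()]
        return state

    def load_state_dict(self, state):
        own = self.parameters()
        buffers = list(self.named_buffers())
        if len(own) + len(buffers) != len(state):
            raise ValueError("state size mismatch")
        for p, d in zip(own, state):
            p.data[...] = d
        for (m, name), d in zip(buffers, state[len(own) :]):
            setattr(m, name, np.array(d, copy=True))

    # complexity accounting -------------------------------------------------
    def macs(self, h, w):
        """(multiply-accumulate count, output (h, w)) for one sample."""
        total = 0
        for c in self._children():
            m, (h, w) = c.macs(h, w)
            total += m
        return total, (h, w)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for l in self.layers:
            x = l(x)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Conv2d(Module):
    """Dense 2-D convolution, zero padding, optional bias."""

    def __init__(self, cin, cout, kernel, stride=1, padding=0, bias=False, rng=None):
        self.cin, self.cout, self.kernel = cin, cout, kernel
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (kernel * kernel * cout))
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin, kernel, kernel)))
        self.bias = Parameter(np.zeros(cout), decay=False) if bias else None

    def forward(self, x):
        b, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        if k == 1 and s == 1 and p == 0:
            x2 = x.transpose(0, 2, 3, 1).reshape(-1, c)
            self._cache = (x2, (b, h, w))
            out = x2 @ self.weight.data.reshape(self.cout, c).T
            if self.bias is not None:
                out += self.bias.data
            return np.ascontiguousarray(
                out.reshape(b, h, w, self.cout).transpose(0, 3, 1, 2)
            )
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        # channels-last so each kernel offset is one BLAS matmul over channels
        xp_cl = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))
        self._cache = (xp_cl, (b, h, w, ho, wo))
        w_cl = self.weight.data.transpose(2, 3, 1, 0)  # (k, k, cin, cout)
        out = np.zeros((b * ho * wo, self.cout), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(
                    xp_cl[:, di : di + ho * s : s, dj : dj + wo * s : s, :]
                ).reshape(-1, self.cin)
                out += xs @ w_cl[di, dj]
        if self.bias is not None:
            out += self.bias.data
        return np.ascontiguousarray(
            out.reshape(b, ho, wo, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.padding
        if k == 1 and s == 1 and p == 0:
            x2, (b, h, w) = self._cache
            g2 = grad.transpose(0, 2, 3, 1).reshape(-1, self.cout)
            self.weight.grad += (g2.T @ x2).reshape(self.weight.data.shape)
            if self.bias is not None:
                self.bias.grad += g2.sum(axis=0)
            dx = g2 @ self.weight.data.reshape(self.cout, self.cin)
            return np.ascontiguousarray(
                dx.reshape(b, h, w, self.cin).transpose(0, 3, 1, 2)
            )
        xp_cl, (b, h, w, ho, wo) = self._cache
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        w_cl = self.weight.data.transpose(2, 3, 1, 0)
        dxp_cl = np.zeros_like(xp_cl)
        dw = np.empty_like(self.weight.data)
        for di in range(k):
            for dj in range(k):
                xs = np.ascontiguousarray(
                    xp_cl[:, di : di + ho * s : s, dj : dj + wo * s : s, :]
                ).reshape(-1, self.cin)
                dw[:, :, di, dj] = (xs.T @ g2).T
                dxs = g2 @ w_cl[di, dj].T
                dxp_cl[:, di : di + ho * s : s, dj : dj + wo * s : s, :] += dxs.reshape(
                    b, ho, wo, self.cin
                )
        self.weight.grad += dw
        dxp = np.ascontiguousarray(dxp_cl.transpose(0, 3, 1, 2))
        if p:
            dxp = dxp[:, :, p : p + h, p : p + w]
        return dxp

    def macs(self, h, w):
        k, s, p = self.kernel, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        return k * k * self.cin * self.cout * ho * wo, (ho, wo)


class DepthwiseConv2d(Module):
    """Per-channel K x K convolution (groups == channels)."""

    def __init__(self, channels, kernel, stride=1, padding=0, rng=None):
        self.channels, self.kernel = channels, kernel
        self.stride, self.padding = stride, padding
        rng = rng or np.random.default_rng(0)
        std = math.sqrt(2.0 / (kernel * kernel))
        self.weight = Parameter(rng.normal(0.0, std, (channels, kernel, kernel)))

    def forward(self, x):
        b, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if not xp.flags.c_contiguous:
            xp = np.ascontiguousarray(xp)
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        self._cache = (xp, (b, h, w, ho, wo))
        if _kernels.HAVE_NUMBA:
            out = np.empty((b, c, ho, wo), dtype=np.float32)
            _kernels.depthwise_fwd(xp, self.weight.data, out, s)
            return out
        out = np.zeros((b, c, ho, wo), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + ho * s : s, dj : dj + wo * s : s]
                out += xs * self.weight.data[None, :, di, dj, None, None]
        return out

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.padding
        xp, (b, h, w, ho, wo) = self._cache
        dxp = np.zeros_like(xp)
        if _kernels.HAVE_NUMBA:
            dw = np.zeros_like(self.weight.data)
            if not grad.flags.c_contiguous:
                grad = np.ascontiguousarray(grad)
            _kernels.depthwise_bwd(xp, self.weight.data, grad, dxp, dw, s)
            self.weight.grad += dw
            if p:
                dxp = dxp[:, :, p : p + h, p : p + w]
            return dxp
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + ho * s : s, dj : dj + wo * s : s]
                self.weight.grad[:, di, dj] += np.einsum("bchw,bchw->c", grad, xs)
                dxp[:, :, di : di + ho * s : s, dj : dj + wo * s : s] += (
                    grad * self.weight.data[None, :, di, dj, None, None]
                )
        if p:
            dxp = dxp[:, :, p : p + h, p : p + w]
        return dxp

    def macs(self, h, w):
        k, s, p = self.kernel, self.stride, self.padding
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        return k * k * self.channels * ho * wo, (ho, wo)


class BatchNorm2d(Module):
    buffer_names = ("running_mean", "running_var")

    def __init__(self, channels, eps=1e-3, momentum=0.1):
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        fast = _kernels.HAVE_NUMBA and x.dtype == np.float32 and x.flags.c_contiguous
        if self.training:
            n = x.shape[0] * x.shape[2] * x.shape[3]
            if fast:
                s, ss = _kernels.bn_stats(x)
                mean = (s / n).astype(np.float32)
                var = np.maximum(ss / n - mean.astype(np.float64) ** 2, 0.0).astype(
                    np.float32
                )
            else:
                mean = x.mean(axis=(0, 2, 3))
                var = np.maximum(
                    np.einsum("bchw,bchw->c", x, x) / n - mean**2, 0.0
                )
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                np.float32
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        mean = np.asarray(mean, dtype=np.float32)
        if fast:
            xhat = np.empty_like(x)
            y = np.empty_like(x)
            _kernels.bn_fwd(x, mean, invstd, self.gamma.data, self.beta.data, xhat, y)
        else:
            xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
            y = self.gamma.data[None, :, None, None] * xhat + self.beta.data[
                None, :, None, None
            ]
        self._cache = (xhat, invstd)
        return y

    def backward(self, grad):
        xhat, invstd = self._cache
        fast = (
            _kernels.HAVE_NUMBA
            and grad.dtype == np.float32
            and grad.flags.c_contiguous
            and xhat.flags.c_contiguous
        )
        if fast:
            gsum0, gdot0 = _kernels.bn_bwd_reduce(grad, xhat)
            self.gamma.grad += gdot0.astype(np.float32)
            self.beta.grad += gsum0.astype(np.float32)
            if not self.training:
                return grad * (self.gamma.data * invstd)[None, :, None, None]
            b, c, h, w = grad.shape
            n = b * h * w
            out = np.empty_like(grad)
            # dx = gamma*invstd/n * (n*grad - sum(grad) - xhat*sum(grad*xhat))
            _kernels.bn_bwd_apply(
                grad,
                xhat,
                self.gamma.data,
                invstd,
                gsum0.astype(np.float32),
                gdot0.astype(np.float32),
                float(n),
                out,
            )
            return out
        self.gamma.grad += np.einsum("bchw,bchw->c", grad, xhat)
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        if not self.training:
            return g * invstd[None, :, None, None]
        b, c, h, w = grad.shape
        n = b * h * w
        gsum = g.sum(axis=(0, 2, 3))[None, :, None, None]
        gdot = np.einsum("bchw,bchw->c", g, xhat)[None, :, None, None]
        return (invstd[None, :, None, None] / n) * (n * g - gsum - xhat * gdot)

    def macs(self, h, w):
        return 0, (h, w)


class SiLU(Module):
    def forward(self, x):
        if _kernels.HAVE_NUMBA and x.dtype == np.float32 and x.flags.c_contiguous:
            y = np.empty_like(x)
            s = np.empty_like(x)
            _kernels.silu_fwd(x.reshape(-1), y.reshape(-1), s.reshape(-1))
            self._cache = (x, s)
            return y
        s = sigmoid(x)
        self._cache = (x, s)
        return x * s

    def backward(self, grad):
        x, s = self._cache
        if _kernels.HAVE_NUMBA and grad.dtype == np.float32:
            out = np.empty_like(grad)
            g = grad if grad.flags.c_contiguous else np.ascontiguousarray(grad)
            _kernels.silu_bwd(x.reshape(-1), s.reshape(-1), g.reshape(-1), out.reshape(-1))
            return out
        return grad * (s * (1.0 + x * (1.0 - s)))

    def macs(self, h, w):
        return 0, (h, w)


class Sigmoid(Module):
    def forward(self, x):
        self._out = sigmoid(x)
        return self._out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)

    def macs(self, h, w):
        return 0, (h, w)


class Linear(Module):
    def __init__(self, cin, cout, bias=True, rng=None, std=None):
        rng = rng or np.random.default_rng(0)
        std = std if std is not None else math.sqrt(1.0 / cin)
        self.cin, self.cout = cin, cout
        self.weight = Parameter(rng.normal(0.0, std, (cout, cin)))
        self.bias = Parameter(np.zeros(cout), decay=False) if bias else None

    def forward(self, x):
        self._x = x
        out = x @ self.weight.data.T
        if self.bias is not None:
            out += self.bias.data
        return out

    def backward(self, grad):
        self.weight.grad += grad.T @ self._x
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data

    def macs(self, h, w):
        return self.cin * self.cout, (h, w)


class Dropout(Module):
    def __init__(self, p, rng=None):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x):
        if not self.training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(np.float32) / (
            1.0 - self.p
        )
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask

    def macs(self, h, w):
        return 0, (h, w)


class GlobalAvgPool(Module):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        b, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)

    def macs(self, h, w):
        return 0, (1, 1)


class AdamW(Module):
    """Adam with decoupled weight decay (applied to decay-flagged params)."""

    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.01):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.decay and self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0


def cross_entropy(logits, labels):
    """Mean softmax cross-entropy; returns (loss, dloss/dlogits)."""
    n = logits.shape[0]
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -float(np.mean(np.log(p[np.arange(n), labels] + eps)))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
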