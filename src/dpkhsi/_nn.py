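"""Minimal numpy neural-network substrate used by the network modules.

Layers follow a channels-last convention: activations are
``(batch, *spatial, channels)`` with 1, 2 or 3 spatial dimensions.  Each
layer implements ``forward(x, train)`` and ``backward(grad)``; parameters
and their gradients are exposed as flat lists for the Adam optimiser.
Everything here is deliberately small and explicit — the networks in this
package have at most a few hundred thousand parameters and train on CPU.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Layer", "ConvND", "ConvTransposeND", "MaxPoolND", "Upsample",
    "BatchNorm", "ReLU", "Flatten", "Dense", "GlobalSpatialMaxPool",
    "Sequential", "Adam", "softmax", "softmax_cross_entropy", "mse_loss",
]


class Layer:
    trainable = True

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _kernel_slices(idx, out_sp):
    return (slice(None),) + tuple(slice(i, i + o) for i, o in zip(idx, out_sp)) + (slice(None),)


class ConvND(Layer):
    """Valid (or 'same') correlation, stride 1, any spatial rank.

    Weights ``W``: ``(out_channels, *kernel, in_channels)``.  The forward
    pass accumulates one matmul per kernel offset — efficient enough for the
    small kernels used here and exactly differentiable by the symmetric
    scatter in :meth:`backward`.
    """

    def __init__(self, in_channels, out_channels, kernel, padding="valid",
                 rng=None, frozen=False):
        self.kernel = tuple(kernel)
        self.padding = padding
        if padding == "same" and any(k % 2 == 0 for k in self.kernel):
            raise ValueError("'same' padding needs odd kernels (center undefined)")
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(self.kernel))
        self.W = rng.standard_normal((out_channels, *self.kernel, in_channels)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.frozen = frozen

    def params(self):
        return [] if self.frozen else [self.W, self.b]

    def grads(self):
        return [] if self.frozen else [self.gW, self.gb]

    def _pad(self, x):
        if self.padding == "valid":
            return x
        pads = [(0, 0)] + [(k // 2, k // 2) for k in self.kernel] + [(0, 0)]
        return np.pad(x, pads)

    def forward(self, x, train=False):
        if x.shape[-1] != self.W.shape[-1]:
            raise ValueError(
                f"channel mismatch: input has {x.shape[-1]}, kernels expect {self.W.shape[-1]}"
            )
        xp = self._pad(x)
        in_sp = xp.shape[1:-1]
        if any(s < k for s, k in zip(in_sp, self.kernel)):
            raise ValueError(f"kernel {self.kernel} exceeds input extent {in_sp}")
        out_sp = tuple(s - k + 1 for s, k in zip(in_sp, self.kernel))
        out = np.zeros((x.shape[0], *out_sp, self.W.shape[0]))
        for idx in product(*[range(k) for k in self.kernel]):
            w = self.W[(slice(None),) + idx + (slice(None),)]      # (K, Cin)
            out += xp[_kernel_slices(idx, out_sp)] @ w.T
        out += self.b
        if train:
            self._xp, self._out_sp = xp, out_sp
        return out

    def backward(self, g):
        xp, out_sp = self._xp, self._out_sp
        self.gW.fill(0.0)
        gx = np.zeros_like(xp)
        gf = g.reshape(-1, g.shape[-1])
        for idx in product(*[range(k) for k in self.kernel]):
            sl = _kernel_slices(idx, out_sp)
            xs = xp[sl].reshape(-1, xp.shape[-1])
            self.gW[(slice(None),) + idx + (slice(None),)] = gf.T @ xs
            gx[sl] += g @ self.W[(slice(None),) + idx + (slice(None),)]
        self.gb[...] = g.reshape(-1, g.shape[-1]).sum(axis=0)
        if self.padding == "same":
            core = (slice(None),) + tuple(
                slice(k // 2, gx.shape[i + 1] - k // 2) for i, k in enumerate(self.kernel)
            ) + (slice(None),)
            gx = gx[core]
        return gx


class ConvTransposeND(Layer):
    """Transposed convolution (the adjoint of valid ConvND), stride 1."""

    def __init__(self, in_channels, out_channels, kernel, rng=None):
        self.kernel = tuple(kernel)
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * int(np.prod(self.kernel))
        self.W = rng.standard_normal((in_channels, *self.kernel, out_channels)) * np.sqrt(2.0 / fan_in)
        self.b = np.zeros(out_channels)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False):
        in_sp = x.shape[1:-1]
        out_sp = tuple(s + k - 1 for s, k in zip(in_sp, self.kernel))
        out = np.zeros((x.shape[0], *out_sp, self.W.shape[-1]))
        for idx in product(*[range(k) for k in self.kernel]):
            w = self.W[(slice(None),) + idx + (slice(None),)]      # (Cin, Cout)
            out[_kernel_slices(idx, in_sp)] += x @ w
        out += self.b
        if train:
            self._x, self._in_sp = x, in_sp
        return out

    def backward(self, g):
        x, in_sp = self._x, self._in_sp
        self.gW.fill(0.0)
        gx = np.zeros_like(x)
        xf = x.reshape(-1, x.shape[-1])
        for idx in product(*[range(k) for k in self.kernel]):
            sl = _kernel_slices(idx, in_sp)
            gs = g[sl].reshape(-1, g.shape[-1])
            self.gW[(slice(None),) + idx + (slice(None),)] = xf.T @ gs
            gx += g[sl] @ self.W[(slice(None),) + idx + (slice(None),)].T
        self.gb[...] = g.reshape(-1, g.shape[-1]).sum(axis=0)
        return gx


class MaxPoolND(Layer):
    """Non-overlapping max pooling; remainders are padded with -inf."""

    trainable = False

    def __init__(self, pool):
        self.pool = tuple(pool)
        if any(p <= 0 for p in self.pool):
            raise ValueError("pool sizes must be positive")

    def forward(self, x, train=False):
        sp = x.shape[1:-1]
        if len(sp) != len(self.pool):
            raise ValueError("pool rank does not match input rank")
        pads = [(0, 0)]
        for s, p in zip(sp, self.pool):
            pads.append((0, (-s) % p))
        pads.append((0, 0))
        xp = np.pad(x, pads, constant_values=-np.inf)
        n, c = xp.shape[0], xp.shape[-1]
        out_sp = tuple(s // p for s, p in zip(xp.shape[1:-1], self.pool))
        # split each spatial axis into (out, pool), then move pool axes last
        shape = [n]
        for o, p in zip(out_sp, self.pool):
            shape += [o, p]
        shape.append(c)
        xr = xp.reshape(shape)
        rank = len(out_sp)
        perm = [0] + [1 + 2 * i for i in range(rank)] + [1 + 2 * rank] + [2 + 2 * i for i in range(rank)]
        xt = np.transpose(xr, perm)                      # (n, *out_sp, c, *pool)
        flat = xt.reshape(*xt.shape[: rank + 2], -1)
        arg = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._flat_shape, self._perm = arg, xt.shape, perm
            self._xp_shape, self._orig_sp = xp.shape, sp
        return out

    def backward(self, g):
        rank = len(self.pool)
        flat = np.zeros(self._flat_shape[: rank + 2] + (int(np.prod(self.pool)),))
        np.put_along_axis(flat, self._arg[..., None], g[..., None], axis=-1)
        xt = flat.reshape(self._flat_shape)
        xr = np.transpose(xt, np.argsort(self._perm))
        gx = xr.reshape(self._xp_shape)
        core = (slice(None),) + tuple(slice(0, s) for s in self._orig_sp) + (slice(None),)
        return gx[core]


class Upsample(Layer):
    """Nearest-neighbour upsampling (decoder counterpart of MaxPoolND)."""

    trainable = False

    def __init__(self, factor):
        self.factor = tuple(factor)

    def forward(self, x, train=False):
        out = x
        for ax, f in enumerate(self.factor, start=1):
            out = np.repeat(out, f, axis=ax)
        if train:
            self._in_sp = x.shape[1:-1]
        return out

    def backward(self, g):
        # sum-pool the gradient back over each repeated block
        for ax, (f, s) in enumerate(zip(self.factor, self._in_sp), start=1):
            shape = list(g.shape)
            shape[ax : ax + 1] = [s, f]
            g = g.reshape(shape).sum(axis=ax + 1)
        return g


class BatchNorm(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.ggamma = np.zeros(channels)
        self.gbeta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.ggamma, self.gbeta]

    def forward(self, x, train=False):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._m = int(np.prod([x.shape[a] for a in axes]))
        return self.gamma * xhat + self.beta

    def backward(self, g):
        xhat, inv, axes, m = self._xhat, self._inv, self._axes, self._m
        self.ggamma[...] = (g * xhat).sum(axis=axes)
        self.gbeta[...] = g.sum(axis=axes)
        gm = g.mean(axis=axes)
        gxm = (g * xhat).mean(axis=axes)
        return self.gamma * inv * (g - gm - xhat * gxm)


class ReLU(Layer):
    trainable = False

    def forward(self, x, train=False):
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    trainable = False

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class GlobalSpatialMaxPool(Layer):
    """Per-channel max over all spatial axes: (N, *spatial, C) -> (N, C)."""

    trainable = False

    def forward(self, x, train=False):
        axes = tuple(range(1, x.ndim - 1))
        if train:
            self._x_shape = x.shape
            self._arg = x.reshape(x.shape[0], -1, x.shape[-1]).argmax(axis=1)
        return x.max(axis=axes)

    def backward(self, g):
        n, c = g.shape
        flat = np.zeros((n, int(np.prod(self._x_shape[1:-1])), c))
        np.put_along_axis(flat, self._arg[:, None, :], g[:, None, :], axis=1)
        return flat.reshape(self._x_shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.standard_normal((in_features, out_features)) * np.sqrt(2.0 / in_features)
        self.b = np.zeros(out_features)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train=train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels0: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits.

    ``labels0`` are 0-based integer class ids.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(p[np.arange(n), labels0] + 1e-12)))
    grad = p.copy()
    grad[np.arange(n), labels0] -= 1.0
    return loss, grad / n


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size
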