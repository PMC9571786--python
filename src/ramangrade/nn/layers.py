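"""Layers with explicit forward/backward passes.

Conventions: inputs are float64 arrays with the batch axis first
((N, C, L) for 1D, (N, C, H, W) for 2D, (N, F) for dense).  ``backward``
consumes the gradient of the loss w.r.t. the layer output, accumulates
parameter gradients in place, and returns the gradient w.r.t. the input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Module:
    def parameters(self) -> list:
        return []

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x, training: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def state_dict(self) -> dict:
        return {str(i): p.value.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match parameter count")
        for i, p in enumerate(params):
            v = np.asarray(state[str(i)])
            if v.shape != p.value.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.value[...] = v


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, training=False):
        for l in self.layers:
            x = l.forward(x, training)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad


class Linear(Module):
    def __init__(self, n_in, n_out, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.W = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class ReLU(Module):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten(Module):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _BatchNorm(Module):
    """Shared batch-norm core; subclasses define the reduction axes."""

    def __init__(self, n_features, momentum=0.1, eps=1e-5):
        self.gamma = Param(np.ones(n_features))
        self.beta = Param(np.zeros(n_features))
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def _expand(self, v):
        shape = [1] * self._ndim
        shape[1] = -1
        return v.reshape(shape)

    def forward(self, x, training=False):
        self._ndim = x.ndim
        # reduce over batch and any spatial axes; axis 1 is the feature axis
        axes = tuple(a for a in range(x.ndim) if a != 1)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._m = np.prod([x.shape[a] for a in axes])
        self._axes = axes
        self._xhat = (x - self._expand(mean)) / self._expand(np.sqrt(var + self.eps))
        self._std = np.sqrt(var + self.eps)
        self._training = training
        return self._expand(self.gamma.value) * self._xhat + self._expand(self.beta.value)

    def backward(self, grad):
        axes = self._axes
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self._expand(self.gamma.value)
        if not self._training:
            return g / self._expand(self._std)
        m = self._m
        sum_g = g.sum(axis=axes, keepdims=True)
        sum_gx = (g * self._xhat).sum(axis=axes, keepdims=True)
        return (g - sum_g / m - self._xhat * sum_gx / m) / self._expand(self._std)


class BatchNorm1d(_BatchNorm):
    """Batch norm over (N,) or (N, L) per feature/channel: input (N, F) or (N, C, L)."""


class BatchNorm2d(_BatchNorm):
    """Batch norm per channel over (N, H, W): input (N, C, H, W)."""


class Conv1d(Module):
    """Valid (no padding), unit-stride 1D convolution: (N, C, L) -> (N, O, L-k+1)."""

    def __init__(self, in_ch, out_ch, kernel, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.W = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel)))
        self.b = Param(np.zeros(out_ch))
        self.kernel = kernel

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        if x.shape[2] < self.kernel:
            raise ValueError(f"input length {x.shape[2]} < kernel {self.kernel}")
        self._x = x
        cols = sliding_window_view(x, self.kernel, axis=2)  # (N, C, L', k)
        self._cols = cols
        out = np.einsum("nclk,ock->nol", cols, self.W.value, optimize=True)
        return out + self.b.value[None, :, None]

    def backward(self, grad):
        self.W.grad += np.einsum("nol,nclk->ock", grad, self._cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        dx = np.zeros_like(self._x)
        for j in range(self.kernel):
            # output position l consumed input position l + j
            dx[:, :, j:j + grad.shape[2]] += np.einsum(
                "nol,oc->ncl", grad, self.W.value[:, :, j], optimize=True)
        return dx


class MaxPool1d(Module):
    def __init__(self, kernel, stride=None):
        self.kernel = kernel
        self.stride = kernel if stride is None else stride

    def forward(self, x, training=False):
        k, s = self.kernel, self.stride
        out_l = (x.shape[2] - k) // s + 1
        if out_l < 1:
            raise ValueError("input too short for pooling window")
        starts = np.arange(out_l) * s
        windows = x[:, :, starts[:, None] + np.arange(k)]  # (N, C, L', k)
        self._arg = windows.argmax(axis=3)
        self._in_shape = x.shape
        self._starts = starts
        return windows.max(axis=3)

    def backward(self, grad):
        dx = np.zeros(self._in_shape)
        n, c, out_l = grad.shape
        ni, ci, li = np.indices((n, c, out_l))
        np.add.at(dx, (ni, ci, self._starts[li] + self._arg), grad)
        return dx


class Conv2d(Module):
    """Strided, zero-padded 2D convolution: (N, C, H, W) -> (N, O, H', W')."""

    def __init__(self, in_ch, out_ch, kernel, rng: np.random.Generator,
                 stride=1, padding=0):
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.W = Param(rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)))
        self.b = Param(np.zeros(out_ch))
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        if xp.shape[2] < k or xp.shape[3] < k:
            raise ValueError("input smaller than kernel")
        cols = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        self._cols = cols  # (N, C, H', W', k, k)
        self._xp_shape = xp.shape
        out = np.einsum("nchwij,ocij->nohw", cols, self.W.value, optimize=True)
        return out + self.b.value[None, :, None, None]

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.padding
        self.W.grad += np.einsum("nohw,nchwij->ocij", grad, self._cols, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros(self._xp_shape)
        n, o, ho, wo = grad.shape
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += np.einsum(
                    "nohw,oc->nchw", grad, self.W.value[:, :, i, j], optimize=True)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2d(Module):
    def __init__(self, kernel, stride=None, padding=0):
        self.kernel = kernel
        self.stride = kernel if stride is None else stride
        self.padding = padding

    def forward(self, x, training=False):
        k, s, p = self.kernel, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = windows.reshape(*windows.shape[:4], k * k)
        self._arg = flat.argmax(axis=4)
        self._xp_shape = xp.shape
        return flat.max(axis=4)

    def backward(self, grad):
        k, s, p = self.kernel, self.stride, self.padding
        dxp = np.zeros(self._xp_shape)
        n, c, ho, wo = grad.shape
        ni, ci, hi, wi = np.indices((n, c, ho, wo))
        ai, aj = self._arg // k, self._arg % k
        np.add.at(dxp, (ni, ci, hi * s + ai, wi * s + aj), grad)
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class GlobalAvgPool2d(Module):
    """(N, C, H, W) -> (N, C) mean over the spatial axes."""

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)
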