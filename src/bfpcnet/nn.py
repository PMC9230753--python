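"""Minimal numpy neural-network engine.

Explicit forward/backward layers (NCHW layout), a torch-like ``Module``
registry for parameter naming/checkpointing, and an Adam optimizer.
Convolution uses im2col + matmul; everything is float32 by default and
fully deterministic given the ``numpy.random.Generator`` used at build
time (weight init) and train time (shuffling, dropout).
"""

from __future__ import annotations

import math

import numpy as np

DTYPE = np.float32


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=DTYPE)
        self.grad = np.zeros_like(self.data)

    @property
    def shape(self):
        return self.data.shape


class Module:
    """Base class: registers child modules and parameters by attribute name.

    Non-trainable state arrays (batchnorm running statistics) are listed
    in ``buffer_names`` so checkpoints carry them alongside the weights.
    """

    buffer_names: tuple = ()

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self.__dict__.get("_params", {}).items():
            yield (prefix + name, p)
        for name, child in self.__dict__.get("_children", {}).items():
            yield from child.named_parameters(prefix + name + ".")

    def named_buffers(self, prefix: str = ""):
        for name in self.buffer_names:
            yield (prefix + name, self)
        for name, child in self.__dict__.get("_children", {}).items():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for child in self.__dict__.get("_children", {}).values():
            yield from child.modules()

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    def state_dict(self) -> dict:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        for key, owner in self.named_buffers():
            out[key] = getattr(owner, key.rsplit(".", 1)[-1]).copy()
        return out

    def load_state_dict(self, state: dict):
        mine = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        missing = (set(mine) | set(buffers)) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in mine.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data[...] = state[k]
        for k, owner in buffers.items():
            attr = k.rsplit(".", 1)[-1]
            setattr(owner, attr, np.asarray(state[k], dtype=DTYPE).copy())

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


# ---------------------------------------------------------------------------
# initializers


def he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(DTYPE)


# ---------------------------------------------------------------------------
# primitive layers


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N,C,H,W) -> column matrix (N*OH*OW, C*k*k) plus output spatial dims."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                      # N,C,OH,OW,k,k
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += d[..., i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=None, rng=None, bias=True):
        if rng is None:
            rng = np.random.default_rng(0)
        if pad is None:
            pad = kernel // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self._cache = None

    def forward(self, x, train=False):
        cols, oh, ow = _im2col(x, self.kernel, self.stride, self.pad)
        w2 = self.weight.data.reshape(self.out_ch, -1)
        out = cols @ w2.T
        if self.bias is not None:
            out += self.bias.data
        n = x.shape[0]
        self._cache = (cols, x.shape, oh, ow)
        return out.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, x_shape, oh, ow = self._cache
        n = x_shape[0]
        d2 = dout.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        self.weight.grad += (d2.T @ cols).reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += d2.sum(axis=0)
        dcols = d2 @ self.weight.data.reshape(self.out_ch, -1)
        return _col2im(dcols, x_shape, self.kernel, self.stride, self.pad)


class BatchNorm2d(Module):
    buffer_names = ("running_mean", "running_var")

    def __init__(self, num_features, momentum=0.1, eps=1e-5):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)
        self._cache = None

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, inv, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        if not train:
            return dxhat * inv[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
        return (inv[None, :, None, None] / m) * (
            m * dxhat - s1[None, :, None, None] - xhat * s2[None, :, None, None])


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dense(Module):
    def __init__(self, in_dim, out_dim, rng=None):
        if rng is None:
            rng = np.random.default_rng(0)
        self.weight = Parameter(he_normal(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim))
        self._x = None

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, dout):
        self.weight.grad += self._x.T @ dout
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.data.T


class GlobalAvgPool2d(Module):
    """(N,C,H,W) -> (N,C)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).copy()


class MaxPool2d(Module):
    """Spatial max pooling; stride 1 with same padding used by spatial attention."""

    def __init__(self, kernel=3, stride=1, pad=None):
        if pad is None:
            pad = kernel // 2 if stride == 1 else 1
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, out.shape)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        idx, x_shape, out_shape = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        n, c, h, w = x_shape
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        oh, ow = out_shape[2], out_shape[3]
        for pos in range(k * k):
            mask = idx == pos
            if not mask.any():
                continue
            i, j = pos // k, pos % k
            dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dout * mask
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class Dropout(Module):
    """Inverted dropout; identity at inference. Draws masks from a shared rng."""

    def __init__(self, rate, rng):
        self.rate = float(rate)
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with Keras-style defaults (eps 1e-7)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0
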