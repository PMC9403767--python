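"""Minimal NumPy layers with exact forward/backward passes.

Tensors are channels-last: 2D batches are ``(B, H, W, C)`` and 3D batches are
``(B, D, H, W, C)``.  Every layer caches what its backward pass needs, so a
layer instance services one forward/backward pair at a time (sufficient for
plain SGD-style training loops).  Convolutions use TensorFlow-style "same"
padding; strides are supported for the downsampling convolutions/poolings of
DenseNet-type encoders.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A named weight array with gradient and trainability/freeze flags."""

    __slots__ = ("name", "value", "grad", "trainable", "frozen")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable   # False for BN running statistics
        self.frozen = False          # set by phase freeze scopes

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    kind = "layer"

    def params(self) -> list[Param]:
        return []

    def forward(self, *xs: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> tuple[np.ndarray, ...]:
        raise NotImplementedError

    def param_counts(self) -> tuple[int, int]:
        """(trainable, non_trainable) — running stats and frozen weights count as non-trainable."""
        tr = nt = 0
        for p in self.params():
            if p.trainable and not p.frozen:
                tr += p.size
            else:
                nt += p.size
        return tr, nt


def _same_pad(n: int, k: int, s: int) -> tuple[int, int]:
    out = -(-n // s)
    total = max((out - 1) * s + k - n, 0)
    return total // 2, total - total // 2


class Conv(Layer):
    """N-dimensional convolution (N = 2 or 3), stride >= 1, "same" padding."""

    kind = "conv"

    def __init__(self, kernel: Sequence[int], cin: int, cout: int, *, bias: bool = False,
                 stride: int | Sequence[int] = 1, rng: np.random.Generator | None = None,
                 name: str = "conv"):
        self.kernel = tuple(int(k) for k in kernel)
        self.cin, self.cout = int(cin), int(cout)
        self.stride = (tuple(stride) if isinstance(stride, (tuple, list))
                       else (int(stride),) * len(self.kernel))
        rng = rng or np.random.default_rng(0)
        fan_in = self.cin * int(np.prod(self.kernel))
        scale = math.sqrt(2.0 / fan_in)  # He initialization for ReLU nets
        w = rng.normal(0.0, scale, size=(self.cin, *self.kernel, self.cout))
        self.w = Param(f"{name}/w", w)
        self.b = Param(f"{name}/b", np.zeros(self.cout)) if bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _offset_slices(self, out_sp):
        for off in np.ndindex(*self.kernel):
            yield off, tuple(slice(o, o + s * n, s)
                             for o, s, n in zip(off, self.stride, out_sp))

    def forward(self, x, training=False):
        # conv as a sum of shifted matmuls over kernel offsets: each offset
        # touches only an (N_out, cin) slice, far cheaper than a full im2col
        d = len(self.kernel)
        assert x.ndim == d + 2, f"conv{d}d expects {d + 2}D input, got {x.ndim}D"
        pads = [(0, 0)] + [_same_pad(n, k, s) for n, k, s in
                           zip(x.shape[1:-1], self.kernel, self.stride)] + [(0, 0)]
        xp = np.pad(x, pads)
        out_sp = tuple(-(-n // s) for n, s in zip(x.shape[1:-1], self.stride))
        n_out = x.shape[0] * int(np.prod(out_sp))
        y = np.zeros((n_out, self.cout), dtype=np.float32)
        w = self.w.value
        for off, sl in self._offset_slices(out_sp):
            w_off = w[(slice(None),) + off + (slice(None),)]        # (cin, cout)
            xs = np.ascontiguousarray(xp[(slice(None),) + sl]).reshape(n_out, self.cin)
            y += xs @ w_off
        if self.b is not None:
            y += self.b.value
        self._cache = (x.shape, pads, xp, out_sp)
        return y.reshape(x.shape[0], *out_sp, self.cout)

    def backward(self, gy):
        x_shape, pads, xp, out_sp = self._cache
        n_out = x_shape[0] * int(np.prod(out_sp))
        gy2 = np.ascontiguousarray(gy).reshape(n_out, self.cout)
        if self.b is not None:
            self.b.grad += gy2.sum(axis=0)
        w = self.w.value
        gxp = np.zeros_like(xp)
        for off, sl in self._offset_slices(out_sp):
            idx = (slice(None),) + off + (slice(None),)
            xs = np.ascontiguousarray(xp[(slice(None),) + sl]).reshape(n_out, self.cin)
            self.w.grad[idx] += xs.T @ gy2
            w_off = w[idx]                                          # (cin, cout)
            gxp[(slice(None),) + sl] += (gy2 @ w_off.T).reshape(
                x_shape[0], *out_sp, self.cin)
        unpad = tuple(slice(p[0], p[0] + n) for p, n in zip(pads[1:-1], x_shape[1:-1]))
        return (gxp[(slice(None),) + unpad],)


class Pool(Layer):
    """Max or average pooling with window/stride and "same" padding."""

    kind = "pool"

    def __init__(self, window: Sequence[int], stride: Sequence[int] | None = None,
                 mode: str = "max"):
        self.window = tuple(int(w) for w in window)
        self.stride = tuple(int(s) for s in (stride or self.window))
        assert mode in ("max", "avg")
        self.mode = mode
        self._cache = None

    def forward(self, x, training=False):
        d = len(self.window)
        pads = [(0, 0)] + [_same_pad(n, k, s) for n, k, s in
                           zip(x.shape[1:-1], self.window, self.stride)] + [(0, 0)]
        fill = -np.inf if self.mode == "max" else 0.0
        xp = np.pad(x, pads, constant_values=fill)
        win = sliding_window_view(xp, self.window, axis=tuple(range(1, d + 1)))
        sub = (slice(None),) + tuple(slice(None, None, s) for s in self.stride)
        win = win[sub]                      # (B, *O, C, *K)
        out_sp = win.shape[1:d + 1]
        K = int(np.prod(self.window))
        flat = win.reshape(*win.shape[:d + 2], K)
        if self.mode == "max":
            am = flat.argmax(axis=-1)
            y = np.take_along_axis(flat, am[..., None], axis=-1)[..., 0]
            self._cache = (x.shape, pads, out_sp, am)
        else:
            y = flat.mean(axis=-1)
            self._cache = (x.shape, pads, out_sp, None)
        return np.ascontiguousarray(y)

    def backward(self, gy):
        x_shape, pads, out_sp, am = self._cache
        d = len(self.window)
        C = x_shape[-1]
        padded_shape = tuple(n + p[0] + p[1] for n, p in zip(x_shape[1:-1], pads[1:-1]))
        gxp = np.zeros((x_shape[0], *padded_shape, C), dtype=np.float32)
        K = int(np.prod(self.window))
        for j, off in enumerate(np.ndindex(*self.window)):
            sl = tuple(slice(o, o + s * n, s) for o, s, n in zip(off, self.stride, out_sp))
            if self.mode == "max":
                contrib = gy * (am == j)
            else:
                contrib = gy / K
            gxp[(slice(None),) + sl] += contrib
        unpad = tuple(slice(p[0], p[0] + n) for p, n in zip(pads[1:-1], x_shape[1:-1]))
        return (gxp[(slice(None),) + unpad],)


class Upsample(Layer):
    """Nearest-neighbour upsampling by integer factors per spatial axis."""

    kind = "upsample"

    def __init__(self, factor: Sequence[int]):
        self.factor = tuple(int(f) for f in factor)

    def forward(self, x, training=False):
        y = x
        for ax, f in enumerate(self.factor, start=1):
            if f > 1:
                y = np.repeat(y, f, axis=ax)
        self._in_shape = x.shape
        return y

    def backward(self, gy):
        d = len(self.factor)
        shape = [gy.shape[0]]
        for n, f in zip(self._in_shape[1:-1], self.factor):
            shape += [n, f]
        shape += [gy.shape[-1]]
        g = gy.reshape(shape)
        return (g.sum(axis=tuple(range(2, 2 * d + 1, 2))),)


class BatchNorm(Layer):
    """Per-channel batch normalization (TF defaults: eps 1e-3, momentum 0.99).

    When frozen, the layer runs in inference mode: moving statistics are used
    and not updated, so a frozen scope's weights stay bit-identical.
    """

    kind = "batchnorm"

    def __init__(self, channels: int, eps: float = 1e-3, momentum: float = 0.99,
                 name: str = "bn"):
        self.channels = int(channels)
        self.eps, self.momentum = eps, momentum
        self.gamma = Param(f"{name}/gamma", np.ones(channels))
        self.beta = Param(f"{name}/beta", np.zeros(channels))
        self.moving_mean = Param(f"{name}/moving_mean", np.zeros(channels), trainable=False)
        self.moving_var = Param(f"{name}/moving_var", np.ones(channels), trainable=False)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training and not self.gamma.frozen:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value = (m * self.moving_mean.value + (1 - m) * mean).astype(np.float32)
            self.moving_var.value = (m * self.moving_var.value + (1 - m) * var).astype(np.float32)
        else:
            mean, var = self.moving_mean.value, self.moving_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, training and not self.gamma.frozen, axes)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, gy):
        xhat, inv, batch_mode, axes = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        gxhat = gy * self.gamma.value
        if not batch_mode:
            return (gxhat * inv,)
        n = np.prod([xhat.shape[a] for a in axes])
        gx = (inv / n) * (n * gxhat - gxhat.sum(axis=axes)
                          - xhat * (gxhat * xhat).sum(axis=axes))
        return (gx.astype(np.float32),)


class ReLU(Layer):
    kind = "relu"

    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return (gy * self._mask,)


class Concat(Layer):
    kind = "concat"

    def __init__(self, axis: int = -1):
        self.axis = axis

    def forward(self, *xs, training=False):
        self._sizes = [x.shape[self.axis] for x in xs]
        return np.concatenate(xs, axis=self.axis)

    def backward(self, gy):
        splits = np.cumsum(self._sizes)[:-1]
        return tuple(np.ascontiguousarray(g) for g in np.split(gy, splits, axis=self.axis))


class Add(Layer):
    kind = "add"

    def forward(self, *xs, training=False):
        self._n = len(xs)
        return sum(xs)

    def backward(self, gy):
        return (gy,) * self._n


class RepeatChannels(Layer):
    """Tile the channel axis n times (e.g. grey CT -> 3-channel backbone input)."""

    kind = "repeat"

    def __init__(self, n: int):
        self.n = int(n)

    def forward(self, x, training=False):
        self._c = x.shape[-1]
        return np.tile(x, (1,) * (x.ndim - 1) + (self.n,))

    def backward(self, gy):
        parts = np.split(gy, self.n, axis=-1)
        return (np.sum(parts, axis=0),)


class StackSlices(Layer):
    """(B, N, H, W, C) -> (B*N, H, W, C); patient-major, then slice index."""

    kind = "stack"

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(-1, *x.shape[2:])

    def backward(self, gy):
        return (gy.reshape(self._shape),)


class UnstackSlices(Layer):
    """(B*N, H, W, C) -> (B, N, H, W, C); inverse of StackSlices for known N."""

    kind = "unstack"

    def __init__(self, stack: StackSlices):
        self._stack = stack

    def forward(self, x, training=False):
        b, n = self._stack._shape[:2]
        return x.reshape(b, n, *x.shape[1:])

    def backward(self, gy):
        return (gy.reshape(-1, *gy.shape[2:]),)


class Softmax(Layer):
    kind = "softmax"

    def __init__(self, axis: int = -1):
        self.axis = axis

    def forward(self, x, training=False):
        z = x - x.max(axis=self.axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=self.axis, keepdims=True)
        self._p = p
        return p

    def backward(self, gy):
        p = self._p
        inner = (gy * p).sum(axis=self.axis, keepdims=True)
        return (p * (gy - inner),)
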