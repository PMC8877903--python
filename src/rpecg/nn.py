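"""Minimal CNN engine in numpy: layers, backprop, and SGD.

Supports exactly what the residual classifiers here need: 2-D convolution
(im2col + GEMM), batch normalization, ReLU, max pooling, global average
pooling, fully connected layers, residual blocks (basic and bottleneck),
softmax cross-entropy, and SGD with momentum and weight decay.

Conventions: activations are (batch, channels, height, width) float32 by
default (float64 available for numerical gradient checks); every layer
implements ``forward(x, train)`` and ``backward(dout)`` and exposes its
trainable tensors through ``params()``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d", "GlobalAvgPool",
    "Flatten", "Linear", "Sequential", "BasicBlock", "Bottleneck",
    "softmax", "softmax_cross_entropy", "SGD",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


def _out_size(n: int, k: int, stride: int, pad: int) -> int:
    return (n + 2 * pad - k) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int,
            pad_value: float = 0.0) -> tuple[np.ndarray, int, int]:
    """Unfold to columns laid out (C, kh, kw, B, oh, ow) so a single GEMM
    over a (C*kh*kw, B*oh*ow) view does the whole batch."""
    B, C, H, W = x.shape
    oh, ow = _out_size(H, kh, stride, pad), _out_size(W, kw, stride, pad)
    if pad:
        xp = np.full((B, C, H + 2 * pad, W + 2 * pad), pad_value, dtype=x.dtype)
        xp[:, :, pad:pad + H, pad:pad + W] = x
    else:
        xp = x
    xt = xp.transpose(1, 0, 2, 3)  # (C, B, H, W) view
    col = np.empty((C, kh, kw, B, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            col[:, i, j] = xt[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return col, oh, ow


def _col2im(dcol: np.ndarray, x_shape: tuple, kh: int, kw: int,
            stride: int, pad: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` for the (C, kh, kw, B, oh, ow) layout."""
    B, C, H, W = x_shape
    oh = _out_size(H, kh, stride, pad)
    ow = _out_size(W, kw, stride, pad)
    dxp = np.zeros((C, B, H + 2 * pad, W + 2 * pad), dtype=dcol.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcol[:, i, j]
    dxp = dxp.transpose(1, 0, 2, 3)
    return dxp[:, :, pad:pad + H, pad:pad + W] if pad else dxp


class Layer:
    def params(self) -> list[Param]:
        return []

    def modules(self) -> list["Layer"]:
        """This layer and all nested sublayers."""
        return [self]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """2-D convolution, He fan-in Gaussian init, no bias (BN follows)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel, kernel))
        self.w = Param(w.astype(dtype), "conv.w")
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._x = None
        self._col = None

    def params(self):
        return [self.w]

    def forward(self, x, train=True):
        self._x = x
        k = self.kernel
        col, oh, ow = _im2col(x, k, k, self.stride, self.pad)
        self._col = col if train else None
        B = x.shape[0]
        O = self.w.data.shape[0]
        colmat = col.reshape(-1, B * oh * ow)                    # (C*k*k, B*L)
        w2 = self.w.data.reshape(O, -1)                          # (O, C*k*k)
        y = w2 @ colmat                                          # (O, B*L)
        return y.reshape(O, B, oh, ow).transpose(1, 0, 2, 3)

    def backward(self, dout):
        x, k = self._x, self.kernel
        B, O = dout.shape[0], dout.shape[1]
        if self._col is not None:
            col = self._col
            oh, ow = dout.shape[2], dout.shape[3]
            self._col = None
        else:
            col, oh, ow = _im2col(x, k, k, self.stride, self.pad)
        colmat = col.reshape(-1, B * oh * ow)
        dmat = np.ascontiguousarray(dout.transpose(1, 0, 2, 3)).reshape(O, -1)
        w2 = self.w.data.reshape(O, -1)
        self.w.grad += (dmat @ colmat.T).reshape(self.w.data.shape)
        dcol = (w2.T @ dmat).reshape(col.shape)
        return _col2im(dcol, x.shape, k, k, self.stride, self.pad)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(ch, dtype=dtype), "bn.gamma")
        self.beta = Param(np.zeros(ch, dtype=dtype), "bn.beta")
        self.running_mean = np.zeros(ch, dtype=dtype)
        self.running_var = np.ones(ch, dtype=dtype)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        if train:
            self._cache = (xhat, std)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, dout):
        xhat, std = self._cache
        axes = (0, 2, 3)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self.gamma.data[None, :, None, None]
        dxhat = dout * g
        dx = (dxhat
              - dxhat.mean(axis=axes, keepdims=True)
              - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True) / m)
        return dx / std[None, :, None, None]


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self._cache = None

    def _padded(self, x):
        p = self.pad
        if not p:
            return x
        xp = np.full((x.shape[0], x.shape[1], x.shape[2] + 2 * p,
                      x.shape[3] + 2 * p), -np.inf, dtype=x.dtype)
        xp[:, :, p:-p, p:-p] = x
        return xp

    def forward(self, x, train=True):
        k, s = self.kernel, self.stride
        oh = _out_size(x.shape[2], k, s, self.pad)
        ow = _out_size(x.shape[3], k, s, self.pad)
        xp = self._padded(x)
        out = np.full((x.shape[0], x.shape[1], oh, ow), -np.inf, dtype=x.dtype)
        for i in range(k):
            for j in range(k):
                np.maximum(out, xp[:, :, i:i + s * oh:s, j:j + s * ow:s], out=out)
        self._cache = (x, out, oh, ow)
        return out

    def backward(self, dout):
        x, out, oh, ow = self._cache
        k, s, p = self.kernel, self.stride, self.pad
        xp = self._padded(x)
        dxp = np.zeros_like(xp)
        used = np.zeros(out.shape, dtype=bool)  # route ties to the first hit
        for i in range(k):
            for j in range(k):
                window = xp[:, :, i:i + s * oh:s, j:j + s * ow:s]
                hit = (window == out) & ~used
                used |= hit
                dxp[:, :, i:i + s * oh:s, j:j + s * ow:s] += dout * hit
        return dxp[:, :, p:p + x.shape[2], p:p + x.shape[3]] if p else dxp


class GlobalAvgPool(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        B, C, H, W = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape).copy() / (H * W)


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.w = Param(w.astype(dtype), "fc.w")
        self.b = Param(np.zeros(out_dim, dtype=dtype), "fc.b")
        self._x = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=True):
        self._x = x
        return x @ self.w.data.T + self.b.data

    def backward(self, dout):
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.data


class _ZeroPadShortcut(Layer):
    """Identity shortcut across a shape change: stride-2 subsample plus
    zero padding of the new channels."""

    def __init__(self, in_ch: int, out_ch: int, stride: int):
        self.in_ch, self.out_ch, self.stride = in_ch, out_ch, stride
        self._x_shape = None

    def forward(self, x, train=True):
        self._x_shape = x.shape
        s = self.stride
        y = x[:, :, ::s, ::s]
        if self.out_ch > self.in_ch:
            padded = np.zeros((y.shape[0], self.out_ch) + y.shape[2:], dtype=x.dtype)
            padded[:, :self.in_ch] = y
            y = padded
        return y

    def backward(self, dout):
        dx = np.zeros(self._x_shape, dtype=dout.dtype)
        s = self.stride
        dx[:, :, ::s, ::s] = dout[:, :self.in_ch]
        return dx


class _Identity(Layer):
    def forward(self, x, train=True):
        return x

    def backward(self, dout):
        return dout


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for lyr in self.layers for p in lyr.params()]

    def modules(self):
        return [self] + [m for lyr in self.layers for m in lyr.modules()]

    def forward(self, x, train=True):
        for lyr in self.layers:
            x = lyr.forward(x, train)
        return x

    def backward(self, dout):
        for lyr in reversed(self.layers):
            dout = lyr.backward(dout)
        return dout


def _make_shortcut(in_ch, out_ch, stride, style, rng, dtype):
    if in_ch == out_ch and stride == 1:
        return _Identity()
    if style == "projection":
        return Sequential([
            Conv2d(in_ch, out_ch, 1, stride=stride, pad=0, rng=rng, dtype=dtype),
            BatchNorm2d(out_ch, dtype=dtype),
        ])
    return _ZeroPadShortcut(in_ch, out_ch, stride)


class BasicBlock(Layer):
    """Two 3x3 convolutions with a skip connection (ResNet-18/34 block)."""

    expansion = 1

    def __init__(self, in_ch: int, ch: int, stride: int = 1,
                 shortcut: str = "projection",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        self.body = Sequential([
            Conv2d(in_ch, ch, 3, stride=stride, pad=1, rng=rng, dtype=dtype),
            BatchNorm2d(ch, dtype=dtype),
            ReLU(),
            Conv2d(ch, ch, 3, stride=1, pad=1, rng=rng, dtype=dtype),
            BatchNorm2d(ch, dtype=dtype),
        ])
        self.shortcut = _make_shortcut(in_ch, ch, stride, shortcut, rng, dtype)
        self.relu = ReLU()

    def params(self):
        return self.body.params() + self.shortcut.params()

    def modules(self):
        return [self] + self.body.modules() + self.shortcut.modules()

    def forward(self, x, train=True):
        return self.relu.forward(self.body.forward(x, train)
                                 + self.shortcut.forward(x, train), train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        return self.body.backward(d) + self.shortcut.backward(d)


class Bottleneck(Layer):
    """1x1 -> 3x3 -> 1x1 block with 4x channel expansion (ResNet-50+)."""

    expansion = 4

    def __init__(self, in_ch: int, ch: int, stride: int = 1,
                 shortcut: str = "projection",
                 rng: np.random.Generator | None = None, dtype=np.float32):
        out_ch = ch * self.expansion
        self.body = Sequential([
            Conv2d(in_ch, ch, 1, stride=1, pad=0, rng=rng, dtype=dtype),
            BatchNorm2d(ch, dtype=dtype),
            ReLU(),
            Conv2d(ch, ch, 3, stride=stride, pad=1, rng=rng, dtype=dtype),
            BatchNorm2d(ch, dtype=dtype),
            ReLU(),
            Conv2d(ch, out_ch, 1, stride=1, pad=0, rng=rng, dtype=dtype),
            BatchNorm2d(out_ch, dtype=dtype),
        ])
        self.shortcut = _make_shortcut(in_ch, out_ch, stride, shortcut, rng, dtype)
        self.relu = ReLU()

    def params(self):
        return self.body.params() + self.shortcut.params()

    def modules(self):
        return [self] + self.body.modules() + self.shortcut.modules()

    def forward(self, x, train=True):
        return self.relu.forward(self.body.forward(x, train)
                                 + self.shortcut.forward(x, train), train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        return self.body.backward(d) + self.shortcut.backward(d)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. logits.

    ``y`` holds integer class indices.
    """
    p = softmax(logits)
    n = len(y)
    eps = np.finfo(p.dtype).tiny
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: list[Param], lr: float = 0.1,
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._vel):
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v -= self.lr * g
            p.data += v
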