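"""Minimal deterministic neural-network primitives in numpy.

The two decoding networks in this package are small (a two-node hidden layer,
and a compact 1-D CNN), so forward and backward passes are written directly
against numpy with an explicit Adam optimizer.  Everything is seeded: weight
initialization takes a ``numpy.random.Generator``, and stochastic layers
(dropout) draw from a generator passed to ``forward``, so a fixed seed gives
bit-identical training runs on one machine.

Conventions: fully connected layers act on (batch, features); convolutional
layers on (batch, channels, length) with 'valid' padding.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Parameter:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool,
                rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    """Affine map (batch, in) -> (batch, out); uniform +-1/sqrt(in) init."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, name: str = "fc"):
        bound = 1.0 / np.sqrt(in_features)
        self.W = Parameter(f"{name}.W",
                           rng.uniform(-bound, bound, (out_features, in_features)))
        self.b = Parameter(f"{name}.b", rng.uniform(-bound, bound, out_features))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad):
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value


class BatchNorm(Layer):
    """Batch normalization over (batch, features) or (batch, channels, len).

    ``axis='feature'`` normalizes each column of a 2-D batch; ``axis='channel'``
    normalizes each channel of a 3-D batch over batch and time jointly.
    Running statistics (momentum 0.1) are used when ``train`` is False.
    """

    def __init__(self, num: int, axis: str = "feature", eps: float = 1e-5,
                 momentum: float = 0.1, name: str = "bn"):
        if axis not in ("feature", "channel"):
            raise ValueError("axis must be 'feature' or 'channel'")
        self.axis = axis
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(num))
        self.beta = Parameter(f"{name}.beta", np.zeros(num))
        self.running_mean = np.zeros(num)
        self.running_var = np.ones(num)

    def parameters(self):
        return [self.gamma, self.beta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, train, rng):
        axes = self._axes(x)
        shp = self._shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shp)) / self._std.reshape(shp)
        self._train = train
        self._n = x.size // mean.size
        return self.gamma.value.reshape(shp) * self._xhat + self.beta.value.reshape(shp)

    def backward(self, grad):
        shp = (1, -1) if grad.ndim == 2 else (1, -1, 1)
        axes = self._axes(grad)
        self.gamma.grad += (grad * self._xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        g = grad * self.gamma.value.reshape(shp)
        if not self._train:
            return g / self._std.reshape(shp)
        n = self._n
        gsum = g.sum(axis=axes).reshape(shp)
        gx_sum = (g * self._xhat).sum(axis=axes).reshape(shp)
        return (g - gsum / n - self._xhat * gx_sum / n) / self._std.reshape(shp)


class Tanh(Layer):
    def forward(self, x, train, rng):
        self._y = np.tanh(x)
        return self._y

    def backward(self, grad):
        return grad * (1.0 - self._y**2)


class HardTanh(Layer):
    """Piecewise-linear saturation clamping to [-1, 1]."""

    def forward(self, x, train, rng):
        self._mask = (x > -1.0) & (x < 1.0)
        return np.clip(x, -1.0, 1.0)

    def backward(self, grad):
        return grad * self._mask


class ELU(Layer):
    """Exponential linear unit: x for x>0, alpha*(exp(x)-1) otherwise."""

    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha

    def forward(self, x, train, rng):
        self._neg = x <= 0
        self._expm1 = np.where(self._neg, np.expm1(np.minimum(x, 0.0)), 0.0)
        return np.where(self._neg, self.alpha * self._expm1, x)

    def backward(self, grad):
        deriv = np.where(self._neg, self.alpha * (self._expm1 + 1.0), 1.0)
        return grad * deriv


class Dropout(Layer):
    """Inverted dropout; identity when not training or p == 0."""

    def __init__(self, p: float = 0.25):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Conv1d(Layer):
    """1-D 'valid' convolution (cross-correlation) over (batch, ch, len)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, name: str = "conv"):
        bound = 1.0 / np.sqrt(in_channels * kernel_size)
        self.kernel_size = kernel_size
        self.W = Parameter(
            f"{name}.W",
            rng.uniform(-bound, bound, (out_channels, in_channels, kernel_size)),
        )
        self.b = Parameter(f"{name}.b", rng.uniform(-bound, bound, out_channels))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train, rng):
        self._x = x
        k = self.kernel_size
        L_out = x.shape[2] - k + 1
        out = np.zeros((x.shape[0], self.W.value.shape[0], L_out))
        for j in range(k):
            out += np.einsum("oc,ncl->nol", self.W.value[:, :, j],
                             x[:, :, j:j + L_out], optimize=True)
        return out + self.b.value[None, :, None]

    def backward(self, grad):
        x = self._x
        k = self.kernel_size
        L_out = grad.shape[2]
        gx = np.zeros_like(x)
        for j in range(k):
            self.W.grad[:, :, j] += np.einsum("nol,ncl->oc", grad,
                                              x[:, :, j:j + L_out], optimize=True)
            gx[:, :, j:j + L_out] += np.einsum("oc,nol->ncl", self.W.value[:, :, j],
                                               grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        return gx


class MaxPool1d(Layer):
    """Max pooling over (batch, ch, len) with the given kernel and stride."""

    def __init__(self, kernel_size: int = 3, stride: int = 2):
        self.kernel_size = kernel_size
        self.stride = stride

    def forward(self, x, train, rng):
        win = sliding_window_view(x, self.kernel_size, axis=2)[:, :, ::self.stride]
        self._argmax = win.argmax(axis=3)
        self._in_shape = x.shape
        return win.max(axis=3)

    def backward(self, grad):
        gx = np.zeros(self._in_shape)
        n, c, L_out = grad.shape
        starts = np.arange(L_out) * self.stride
        idx = self._argmax + starts[None, None, :]
        ni = np.arange(n)[:, None, None]
        ci = np.arange(c)[None, :, None]
        np.add.at(gx, (ni, ci, idx), grad)
        return gx


class Flatten(Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]

    def forward(self, x, train=False, rng=None):
        for l in self.layers:
            x = l.forward(x, train, rng)
        return x

    def backward(self, grad):
        for l in reversed(self.layers):
            grad = l.backward(grad)
        return grad

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8, no weight decay)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def pearson_loss(pred: np.ndarray, target: np.ndarray, *,
                 eps: float = 1e-8, with_grad: bool = False):
    """``1 - r`` where r is the Pearson correlation over the batch.

    Range [0, 2]; invariant to positive affine rescaling of either argument.
    A variance guard ``eps`` stabilizes near-constant batches; an exactly
    constant input raises.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.size != target.size or pred.size < 2:
        raise ValueError("pearson_loss needs two equal-length batches, n >= 2")
    pc = pred - pred.mean()
    tc = target - target.mean()
    sp2 = pc @ pc
    st2 = tc @ tc
    if sp2 == 0 or st2 == 0:
        raise ValueError("zero-variance input: Pearson correlation undefined")
    sp = np.sqrt(sp2 + eps)
    st = np.sqrt(st2 + eps)
    r = (pc @ tc) / (sp * st)
    loss = 1.0 - r
    if not with_grad:
        return loss
    grad = -(tc / (sp * st) - r * pc / (sp * sp))
    grad -= grad.mean()
    return loss, grad


def bce_with_logits(logits: np.ndarray, labels: np.ndarray, *,
                    with_grad: bool = False):
    """Mean binary cross-entropy on raw scores (numerically stable form)."""
    z = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if z.size != y.size:
        raise ValueError("logits and labels differ in length")
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    if not with_grad:
        return loss
    grad = (1.0 / (1.0 + np.exp(-z)) - y) / z.size
    return loss, grad
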