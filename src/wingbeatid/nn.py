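"""Minimal NumPy neural-network layer library with explicit backprop.

Implements exactly the layer zoo the wingbeat classifiers need: 1-D/2-D
convolution (stride 1, "same" padding), batch normalization, ReLU,
max/global-average pooling, dropout, linear layers and the Adam optimizer.
Forward passes cache what the matching ``backward`` needs; gradients are
accumulated into ``Parameter.grad`` buffers.

Convolutions are evaluated as matrix products over sliding-window views so
the heavy lifting runs inside BLAS. Default parameter dtype is float32;
``dtype=np.float64`` is supported for numerical gradient checking.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DEFAULT_DTYPE = np.float32


class Parameter:
    """A trainable array with an accumulated-gradient buffer."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base class: layers implement forward/backward and expose parameters."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for child in self.children():
            params.extend(child.parameters())
        return params

    def children(self) -> list["Module"]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.forward(x, train=train)

    def state(self) -> list[np.ndarray]:
        """Snapshot of all parameter values plus running statistics."""
        arrays = [p.value.copy() for p in self.parameters()]
        for bn in _batchnorms(self):
            arrays.append(bn.running_mean.copy())
            arrays.append(bn.running_var.copy())
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrays):
            p.value[...] = a
        tail = arrays[len(params):]
        for bn, (m, v) in zip(_batchnorms(self), zip(tail[0::2], tail[1::2])):
            bn.running_mean[...] = m
            bn.running_var[...] = v


def _batchnorms(module: Module) -> list["Module"]:
    found = []
    stack = [module]
    while stack:
        m = stack.pop()
        if isinstance(m, (BatchNorm1d, BatchNorm2d)):
            found.append(m)
        stack.extend(reversed(m.children()))
    return found


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


# ---------------------------------------------------------------------------
# 1-D layers (inputs shaped (batch, channels, length))
# ---------------------------------------------------------------------------

class Conv1d(Module):
    """Stride-1 cross-correlation with 'same' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, kernel_size),
                                         in_channels * kernel_size, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self._pad = ((kernel_size - 1) // 2, kernel_size // 2)

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        pl, pr = self._pad
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        self._xp = xp
        v = sliding_window_view(xp, self.kernel_size, axis=2)  # (N, C, L, K)
        y = np.tensordot(v, self.weight.value, axes=([1, 3], [1, 2]))  # (N, L, F)
        y = np.ascontiguousarray(y.transpose(0, 2, 1))
        y += self.bias.value[:, None]
        return y

    def backward(self, grad):
        xp = self._xp
        n, _, lout = grad.shape
        v = sliding_window_view(xp, self.kernel_size, axis=2)
        self.weight.grad += np.einsum('nfl,nclk->fck', grad, v, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2))
        dxp = np.zeros_like(xp)
        w = self.weight.value
        for j in range(self.kernel_size):
            # dxp[:, c, l+j] += sum_f grad[:, f, l] * w[f, c, j]
            dxp[:, :, j:j + lout] += np.tensordot(
                w[:, :, j], grad, axes=(0, 1)).transpose(1, 0, 2)
        pl = self._pad[0]
        return dxp[:, :, pl:pl + xp.shape[2] - sum(self._pad)]


class BatchNorm1d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DEFAULT_DTYPE):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) / std[:, None]
        self._cache = (xhat, std, x.shape[0] * x.shape[2])
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, grad):
        xhat, std, m = self._cache
        dbeta = grad.sum(axis=(0, 2))
        dgamma = (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        coef = self.gamma.value / std
        return coef[:, None] * (grad - dbeta[:, None] / m - xhat * (dgamma[:, None] / m))


class ReLU(Module):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1d(Module):
    """Non-overlapping max pooling (window = stride); trailing remainder dropped."""

    def __init__(self, window: int = 2):
        self.window = window

    def forward(self, x, train=False):
        n, c, l = x.shape
        lo = l // self.window
        xr = x[:, :, :lo * self.window].reshape(n, c, lo, self.window)
        self._idx = xr.argmax(axis=3)
        self._in_len = l
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, grad):
        n, c, lo = grad.shape
        dxr = np.zeros((n, c, lo, self.window), dtype=grad.dtype)
        np.put_along_axis(dxr, self._idx[..., None], grad[..., None], axis=3)
        dx = np.zeros((n, c, self._in_len), dtype=grad.dtype)
        dx[:, :, :lo * self.window] = dxr.reshape(n, c, lo * self.window)
        return dx


class MaxPoolSame1d(Module):
    """Length-preserving max pooling (stride 1, odd window, -inf padding)."""

    def __init__(self, window: int = 3):
        if window % 2 == 0:
            raise ValueError("window must be odd for same-length pooling")
        self.window = window

    def forward(self, x, train=False):
        p = self.window // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf)
        v = sliding_window_view(xp, self.window, axis=2)
        self._idx = v.argmax(axis=3)
        self._shape = x.shape
        return np.take_along_axis(v, self._idx[..., None], axis=3)[..., 0]

    def backward(self, grad):
        n, c, l = self._shape
        p = self.window // 2
        dxp = np.zeros((n, c, l + 2 * p), dtype=grad.dtype)
        for j in range(self.window):
            dxp[:, :, j:j + l] += grad * (self._idx == j)
        return dxp[:, :, p:p + l]


class GlobalAvgPool1d(Module):
    def forward(self, x, train=False):
        if x.shape[2] == 0:
            raise ValueError("cannot average-pool an empty temporal axis "
                             "(input too short for the pooling stack?)")
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._len, axis=2) / self._len


class Dropout(Module):
    """Inverted dropout; identity outside training."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask.astype(grad.dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        self.weight = Parameter(_he_init(rng, (in_features, out_features),
                                         in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype))

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        self.weight.grad += self._x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T


# ---------------------------------------------------------------------------
# 2-D layers (inputs shaped (batch, channels, height, width))
# ---------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=DEFAULT_DTYPE):
        k = kernel_size
        self.kernel_size = k
        self.weight = Parameter(_he_init(rng, (out_channels, in_channels, k, k),
                                         in_channels * k * k, dtype))
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self._pad = ((k - 1) // 2, k // 2)

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        pl, pr = self._pad
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr), (pl, pr)))
        self._xp = xp
        k = self.kernel_size
        v = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
        y = np.tensordot(v, self.weight.value, axes=([1, 4, 5], [1, 2, 3]))
        y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
        y += self.bias.value[:, None, None]
        return y

    def backward(self, grad):
        xp = self._xp
        k = self.kernel_size
        _, _, h, w = grad.shape
        v = sliding_window_view(xp, (k, k), axis=(2, 3))
        self.weight.grad += np.einsum('nfhw,nchwij->fcij', grad, v, optimize=True)
        self.bias.grad += grad.sum(axis=(0, 2, 3))
        dxp = np.zeros_like(xp)
        wv = self.weight.value
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += np.tensordot(
                    wv[:, :, i, j], grad, axes=(0, 1)).transpose(1, 0, 2, 3)
        pl = self._pad[0]
        return dxp[:, :, pl:pl + h, pl:pl + w]


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=DEFAULT_DTYPE):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) / std[:, None, None]
        self._cache = (xhat, std, x.shape[0] * x.shape[2] * x.shape[3])
        return self.gamma.value[:, None, None] * xhat + self.beta.value[:, None, None]

    def backward(self, grad):
        xhat, std, m = self._cache
        dbeta = grad.sum(axis=(0, 2, 3))
        dgamma = (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dbeta
        self.gamma.grad += dgamma
        coef = (self.gamma.value / std)[:, None, None]
        return coef * (grad - dbeta[:, None, None] / m - xhat * (dgamma[:, None, None] / m))


class MaxPool2d(Module):
    """Non-overlapping square max pooling; trailing remainders dropped."""

    def __init__(self, window: int = 2):
        self.window = window

    def forward(self, x, train=False):
        s = self.window
        n, c, h, w = x.shape
        ho, wo = h // s, w // s
        xr = x[:, :, :ho * s, :wo * s].reshape(n, c, ho, s, wo, s)
        m1 = xr.max(axis=5)
        self._i1 = xr.argmax(axis=5)
        self._i2 = m1.argmax(axis=3)
        self._in_shape = x.shape
        return np.take_along_axis(m1, self._i2[:, :, :, None], axis=3)[:, :, :, 0]

    def backward(self, grad):
        s = self.window
        n, c, h, w = self._in_shape
        ho, wo = h // s, w // s
        dm1 = np.zeros((n, c, ho, s, wo), dtype=grad.dtype)
        np.put_along_axis(dm1, self._i2[:, :, :, None], grad[:, :, :, None], axis=3)
        dxr = np.zeros((n, c, ho, s, wo, s), dtype=grad.dtype)
        np.put_along_axis(dxr, self._i1[..., None], dm1[..., None], axis=5)
        dx = np.zeros((n, c, h, w), dtype=grad.dtype)
        dx[:, :, :ho * s, :wo * s] = dxr.reshape(n, c, ho * s, wo * s)
        return dx


class GlobalAvgPool2d(Module):
    def forward(self, x, train=False):
        if x.shape[2] * x.shape[3] == 0:
            raise ValueError("cannot average-pool an empty image "
                             "(input too small for the pooling stack?)")
        self._hw = x.shape[2] * x.shape[3]
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / self._hw


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

class Sequential(Module):
    def __init__(self, layers: list[Module]):
        self.layers = list(layers)

    def children(self):
        return self.layers

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on raw scores; returns (loss, dloss/dlogits).

    Uses the log-sum-exp form so large scores cannot overflow.
    """
    z = logits.astype(np.float64).ravel()
    y = labels.astype(np.float64).ravel()
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / z.size).reshape(logits.shape)
    return loss, grad


class Network(Module):
    """A feature body plus a linear head producing one logit per record.

    ``predict_proba`` applies the sigmoid; training code consumes raw
    logits through ``forward`` together with :func:`bce_with_logits`.
    """

    def __init__(self, body: Module, head: Module):
        self.body = body
        self.head = head

    def children(self):
        return [self.body, self.head]

    def forward(self, x, train=False):
        return self.head.forward(self.body.forward(x, train=train), train=train)

    def backward(self, grad):
        return self.body.backward(self.head.backward(grad))

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Per-record probability of the positive class, in evaluation mode."""
        out = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i:i + batch_size], train=False)
            out.append(sigmoid(logits).ravel())
        return np.concatenate(out) if out else np.empty(0)

    def clone_state(self) -> list[np.ndarray]:
        return copy.deepcopy(self.state())


class Adam:
    """Adam optimizer; the learning rate is supplied per step (for CLR)."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.value.dtype)
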