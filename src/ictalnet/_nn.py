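"""Minimal NumPy layer library with manual backpropagation.

Only what the residual 1-D CNN needs: convolution (im2col + BLAS matmul),
batch normalization, ReLU, inverted dropout, global average pooling and a
dense layer.  All computation is float32.

Activations are channels-last, shape ``(batch, time, channels)``: im2col
then reduces to ``kernel`` slice copies with a contiguous inner axis and the
matmul reshapes are views, which is what makes CPU training tractable.
Layers cache activations during a training forward pass and release them
after backward.
"""

from __future__ import annotations

import numpy as np

from ._kernels import (
    bn_backward_dx,
    bn_backward_reduce,
    bn_forward,
    bn_stats,
    col2im,
    im2col,
)


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Conv1d:
    """1-D convolution with 'same'-style zero padding, channels-last.

    Output length is ``ceil(L / stride)`` regardless of kernel size, so the
    temporal extent of the network is determined solely by the strides.
    Weights are stored as a ``(kernel * c_in, c_out)`` matrix with rows
    ordered ``(tap, channel)``.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        *,
        rng: np.random.Generator,
        name: str = "conv",
        main_path: bool = True,
        input_grad: bool = True,
    ):
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.main_path = main_path
        self.input_grad = input_grad
        fan_in = c_in * kernel
        std = np.sqrt(2.0 / fan_in)  # He initialization
        self.W = Param(rng.standard_normal((fan_in, c_out)) * std, f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cache = None
        self._buffers: dict[str, np.ndarray] = {}

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_len(self, length: int) -> int:
        return -(-length // self.stride)

    def _geometry(self, L: int) -> tuple[int, int, int]:
        l_out = self.out_len(L)
        pad_total = max((l_out - 1) * self.stride + self.kernel - L, 0)
        return l_out, pad_total // 2, pad_total

    def _buffer(self, key: str, shape: tuple[int, ...]) -> np.ndarray:
        # persistent scratch: avoids re-faulting large fresh pages every step
        buf = self._buffers.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._buffers[key] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, L, C = x.shape
        k, s = self.kernel, self.stride
        l_out, pl, pad_total = self._geometry(L)
        xp = np.pad(x, ((0, 0), (pl, pad_total - pl), (0, 0)))
        cols = self._buffer("cols", (B, l_out, k, C))
        im2col(xp, cols, s)
        y = cols.reshape(B * l_out, k * C) @ self.W.value + self.b.value
        if train:
            self._cache = ((B, L, C), pl, pad_total, l_out)
        return y.reshape(B, l_out, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (B, L, C), pl, pad_total, l_out = self._cache
        self._cache = None
        k, s = self.kernel, self.stride
        cols = self._buffers["cols"]  # still holds this step's activations
        dmat = np.ascontiguousarray(dy).reshape(B * l_out, self.c_out)
        cols_mat = cols.reshape(B * l_out, k * C)
        self.W.grad += cols_mat.T @ dmat
        self.b.grad += dmat.sum(axis=0)
        if not self.input_grad:  # first layer: nothing upstream needs dx
            return None
        dcols = self._buffer("dcols", (B, l_out, k, C))
        np.matmul(dmat, self.W.value.T, out=dcols.reshape(B * l_out, k * C))
        dxp = self._buffer("dxp", (B, L + pad_total, C))
        dxp.fill(0.0)
        col2im(dcols, dxp, s)
        return dxp[:, pl : pl + L, :]


class BatchNorm1d:
    """Per-channel batch normalization over (batch, time)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(c), f"{name}.gamma")
        self.beta = Param(np.zeros(c), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None
        self._buffers: dict[str, np.ndarray] = {}

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _buffer(self, key: str, shape: tuple[int, ...]) -> np.ndarray:
        buf = self._buffers.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=np.float32)
            self._buffers[key] = buf
        return buf

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            return (
                self.gamma.value * inv * (x - self.running_mean) + self.beta.value
            ).astype(np.float32)
        shape = x.shape
        c = shape[-1]
        x2 = np.ascontiguousarray(x, dtype=np.float32).reshape(-1, c)
        n = x2.shape[0]
        total, total_sq = bn_stats(x2)
        mu = total / n
        var = np.maximum(total_sq / n - mu * mu, 0.0)
        self.running_mean += self.momentum * (mu.astype(np.float32) - self.running_mean)
        self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        xhat2 = self._buffer("xhat", x2.shape)
        y2 = self._buffer("y", x2.shape)
        bn_forward(
            x2, mu.astype(np.float32), inv_std, self.gamma.value, self.beta.value,
            xhat2, y2,
        )
        self._cache = (inv_std, shape)
        return y2.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        inv_std, shape = self._cache
        self._cache = None
        c = shape[-1]
        dy2 = np.ascontiguousarray(dy, dtype=np.float32).reshape(-1, c)
        xhat2 = self._buffers["xhat"]
        n = dy2.shape[0]
        dbeta, dgamma = bn_backward_reduce(dy2, xhat2)
        self.beta.grad += dbeta.astype(np.float32)
        self.gamma.grad += dgamma.astype(np.float32)
        # means of dxhat and dxhat*xhat, expressed via the reductions above
        m1 = (dbeta * self.gamma.value.astype(np.float64) / n).astype(np.float32)
        m2 = (dgamma * self.gamma.value.astype(np.float64) / n).astype(np.float32)
        dx2 = self._buffer("dx", dy2.shape)
        bn_backward_dx(dy2, xhat2, self.gamma.value, inv_std, m1, m2, dx2)
        return dx2.reshape(shape)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask, self._mask = self._mask, None
        return dy * mask


class Dropout:
    """Inverted dropout; identity when rate is 0 or in inference mode."""

    def __init__(self, rate: float):
        self.rate = rate
        self._mask = None

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep).astype(np.float32) / keep
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        mask, self._mask = self._mask, None
        return dy * mask


class Dense:
    def __init__(self, c_in: int, c_out: int, *, rng: np.random.Generator, name: str = "fc"):
        std = np.sqrt(2.0 / c_in)
        self.W = Param(rng.standard_normal((c_in, c_out)) * std, f"{name}.W")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self._cache = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._cache = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, self._cache = self._cache, None
        self.W.grad += x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """(B, L, C) -> (B, C)."""
    return x.mean(axis=1)


def global_avg_pool_backward(dy: np.ndarray, length: int) -> np.ndarray:
    return np.repeat(dy[:, None, :], length, axis=1) / np.float32(length)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class SGD:
    """Plain stochastic gradient descent with optional momentum/weight decay."""

    def __init__(self, params: list[Param], momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params] if momentum else None

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self, lr: float) -> None:
        lr = np.float32(lr)
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay:
                g = g + np.float32(self.weight_decay) * p.value
            if self._velocity is not None:
                v = self._velocity[i]
                v *= np.float32(self.momentum)
                v -= lr * g
                p.value += v
            else:
                p.value -= lr * g
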