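"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the operations the frame predictor needs — 3x3 and 1x1
convolutions, 2x max-pooling, 2x transposed convolution, GroupNorm, ReLU and
sigmoid — each as a layer object with ``forward(x)`` / ``backward(dy)`` and
explicit parameter/gradient storage, plus an Adam optimiser.  Tensors are
(N, C, H, W).  Gradient correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Param", "Module", "Conv2d", "MaxPool2", "ConvTranspose2", "GroupNorm",
    "ReLU", "Sigmoid", "Sequential", "Adam",
]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Module:
    """Base layer: subclasses implement forward/backward and list params."""

    def params(self) -> list:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.params())
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def n_params(self) -> int:
        return sum(p.value.size for p in self.params())


class Conv2d(Module):
    """Convolution with kernel 3 (pad 1, stride 1) or kernel 1."""

    def __init__(self, cin: int, cout: int, ksize: int = 3,
                 rng: np.random.Generator | None = None,
                 dtype=np.float64):
        if ksize not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        rng = rng or np.random.default_rng()
        fan_in = cin * ksize * ksize
        std = math.sqrt(2.0 / fan_in)  # He init for ReLU nets
        bound = 1.0 / math.sqrt(fan_in)
        self.ksize = ksize
        self.W = Param((rng.standard_normal((cout, cin, ksize, ksize)) * std
                        ).astype(dtype))
        self.b = Param(rng.uniform(-bound, bound, cout).astype(dtype))
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        O = self.W.value.shape[0]
        if self.ksize == 1:
            Wm = self.W.value.reshape(O, C)
            xf = x.transpose(1, 0, 2, 3).reshape(C, -1)
            y = (Wm @ xf).reshape(O, N, H, W).transpose(1, 0, 2, 3)
            self._cache = (xf, (N, C, H, W))
        else:
            xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
            view = np.lib.stride_tricks.sliding_window_view(xp, (3, 3),
                                                            axis=(2, 3))
            cols = view.transpose(1, 4, 5, 0, 2, 3).reshape(C * 9, -1)
            Wm = self.W.value.reshape(O, C * 9)
            y = (Wm @ cols).reshape(O, N, H, W).transpose(1, 0, 2, 3)
            self._cache = (cols, (N, C, H, W))
        return y + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (N, C, H, W) = self._cache
        O = self.W.value.shape[0]
        dyf = dy.transpose(1, 0, 2, 3).reshape(O, -1)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        if self.ksize == 1:
            Wm = self.W.value.reshape(O, C)
            self.W.grad += (dyf @ cols.T).reshape(self.W.value.shape)
            dx = (Wm.T @ dyf).reshape(C, N, H, W).transpose(1, 0, 2, 3)
            return dx
        Wm = self.W.value.reshape(O, C * 9)
        self.W.grad += (dyf @ cols.T).reshape(self.W.value.shape)
        dcols = (Wm.T @ dyf).reshape(C, 3, 3, N, H, W)
        dxp = np.zeros((N, C, H + 2, W + 2), dtype=dy.dtype)
        for di in range(3):
            for dj in range(3):
                dxp[:, :, di:di + H, dj:dj + W] += \
                    dcols[:, di, dj].transpose(1, 0, 2, 3)
        return dxp[:, :, 1:-1, 1:-1]


class MaxPool2(Module):
    """2x2 max pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(N, C, H // 2, W // 2, 4)
        self._idx = np.argmax(flat, axis=-1)
        self._shape = (N, C, H, W)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, C, H, W = self._shape
        dflat = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(N, C, H, W)


class ConvTranspose2(Module):
    """2x2 transposed convolution, stride 2 (doubles spatial size)."""

    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        rng = rng or np.random.default_rng()
        std = math.sqrt(2.0 / cin)
        bound = 1.0 / math.sqrt(cin)
        self.W = Param((rng.standard_normal((cin, cout, 2, 2)) * std
                        ).astype(dtype))
        self.b = Param(rng.uniform(-bound, bound, cout).astype(dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        O = self.W.value.shape[1]
        self._x = x
        y = np.empty((N, O, 2 * H, 2 * W), dtype=x.dtype)
        for di in range(2):
            for dj in range(2):
                y[:, :, di::2, dj::2] = np.tensordot(
                    x, self.W.value[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.zeros_like(x)
        for di in range(2):
            for dj in range(2):
                dphase = dy[:, :, di::2, dj::2]  # (N, O, H, W)
                self.W.grad[:, :, di, dj] += np.tensordot(
                    x, dphase, axes=([0, 2, 3], [0, 2, 3]))
                dx += np.tensordot(dphase, self.W.value[:, :, di, dj],
                                   axes=([1], [1])).transpose(0, 3, 1, 2)
        return dx


class GroupNorm(Module):
    """Group normalisation with per-channel affine parameters.

    ``channels_per_group`` follows the 16-channels-per-group convention; when
    the layer width is not divisible by it, the greatest common divisor is
    used so groups always tile the channels exactly.
    """

    def __init__(self, channels: int, channels_per_group: int = 16,
                 eps: float = 1e-5, dtype=np.float64):
        cpg = math.gcd(channels, channels_per_group) \
            if channels % channels_per_group else channels_per_group
        self.groups = channels // cpg
        self.eps = eps
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))

    def forward(self, x: np.ndarray) -> np.ndarray:
        N, C, H, W = x.shape
        g = self.groups
        xg = x.reshape(N, g, -1)
        mu = xg.mean(axis=2, keepdims=True)
        var = xg.var(axis=2, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = ((xg - mu) * inv).reshape(N, C, H, W)
        self._cache = (xhat, inv, (N, C, H, W))
        return xhat * self.gamma.value[None, :, None, None] \
            + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, (N, C, H, W) = self._cache
        g = self.groups
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = (dy * self.gamma.value[None, :, None, None]).reshape(N, g, -1)
        xh = xhat.reshape(N, g, -1)
        m1 = dxhat.mean(axis=2, keepdims=True)
        m2 = (dxhat * xh).mean(axis=2, keepdims=True)
        dx = inv * (dxhat - m1 - xh * m2)
        return dx.reshape(N, C, H, W)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with an externally supplied learning rate per step."""

    def __init__(self, params: list, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)
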