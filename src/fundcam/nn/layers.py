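"""Minimal differentiable layers on NumPy arrays.

All layers operate on batches laid out ``(N, C, H, W)`` (or ``(N, F)`` for
dense layers) in float64.  Each layer caches what its backward pass needs
during :meth:`forward`; :meth:`backward` consumes the cache, accumulates
parameter gradients in ``self.grads`` and returns the gradient with respect
to its input.

The backward pass takes a ``guided`` flag: when set, every ReLU applies the
guided-backpropagation rule — in addition to the usual gating on positive
forward activations, incoming gradients below zero are not propagated.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Linear",
    "Residual",
]


class Layer:
    """Base class: parameter-free identity."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray, guided: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)

    def iter_layers(self):
        yield self


class Conv2d(Layer):
    """2-D cross-correlation with square kernel, stride and zero padding."""

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * ksize * ksize
        self.params = {
            "W": rng.standard_normal((out_ch, in_ch, ksize, ksize)) * np.sqrt(2.0 / fan_in),
            "b": np.zeros(out_ch),
        }
        self.zero_grad()
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        out = np.einsum("nchwkl,ockl->nohw", win, self.params["W"], optimize=True)
        out += self.params["b"][:, None, None]
        self._cache = (x.shape, xp.shape, win)
        return out

    def backward(self, grad_out: np.ndarray, guided: bool = False) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        x_shape, xp_shape, win = self._cache
        W = self.params["W"]
        self.grads["W"] += np.einsum("nchwkl,nohw->ockl", win, grad_out, optimize=True)
        self.grads["b"] += grad_out.sum(axis=(0, 2, 3))
        n_out_h, n_out_w = grad_out.shape[2:]
        gx = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + s * n_out_h:s, j:j + s * n_out_w:s] += np.einsum(
                    "nohw,oc->nchw", grad_out, W[:, :, i, j], optimize=True)
        if p:
            gx = gx[:, :, p:p + x_shape[2], p:p + x_shape[3]]
        return gx


class ReLU(Layer):
    def __init__(self) -> None:
        super().__init__()
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad_out: np.ndarray, guided: bool = False) -> np.ndarray:
        g = np.where(self._mask, grad_out, 0.0)
        if guided:
            # guided rule: negative incoming gradients are not propagated
            g = np.where(g > 0, g, 0.0)
        return g


class MaxPool2d(Layer):
    def __init__(self, ksize: int = 2, stride: int | None = None, pad: int = 0) -> None:
        super().__init__()
        self.ksize = ksize
        self.stride = stride or ksize
        self.pad = pad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(win.shape[:4] + (k * k,))
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, xp.shape, idx)
        return out

    def backward(self, grad_out: np.ndarray, guided: bool = False) -> np.ndarray:
        k, s, p = self.ksize, self.stride, self.pad
        x_shape, xp_shape, idx = self._cache
        N, C, Ho, Wo = grad_out.shape
        gx = np.zeros(xp_shape)
        n = np.arange(N)[:, None, None, None]
        c = np.arange(C)[None, :, None, None]
        h = np.arange(Ho)[None, None, :, None]
        w = np.arange(Wo)[None, None, None, :]
        rows = h * s + idx // k
        cols = w * s + idx % k
        np.add.at(gx, (n, c, rows, cols), grad_out)
        if p:
            gx = gx[:, :, p:p + x_shape[2], p:p + x_shape[3]]
        return gx


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""

    def __init__(self) -> None:
        super().__init__()
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad_out: np.ndarray, guided: bool = False) -> np.ndarray:
        N, C, H, W = self._in_shape
        return np.broadcast_to(grad_out[:, :, None, None], self._in_shape) / (H * W)


class Linear(Layer):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "W": rng.standard_normal((out_f, in_f)) * np.sqrt(1.0 / in_f),
            "b": np.zeros(out_f),
        }
        self.zero_grad()
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad_out: np.ndarray, guided: bool = False) -> np.ndarray:
        self.grads["W"] += grad_out.T @ self._x
        self.grads["b"] += grad_out.sum(axis=0)
        return grad_out @ self.params["W"]


class Residual(Layer):
    """Residual block: ``out = ReLU(body(x) + shortcut(x))``.

    ``shortcut=None`` means an identity skip; otherwise it is a projection
    (1x1 conv) matching the body's output shape.
    """

    def __init__(self, body: list[Layer], shortcut: list[Layer] | None = None) -> None:
        super().__init__()
        self.body = body
        self.shortcut = shortcut
        self.post = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for layer in self.body:
            h = layer.forward(h)
        s = x
        if self.shortcut is not None:
            for layer in self.shortcut:
                s = layer.forward(s)
        return self.post.forward(h + s)

    def backward(self, grad_out: np.ndarray, guided: bool = False) -> np.ndarray:
        g = self.post.backward(grad_out, guided=guided)
        gb = g
        for layer in reversed(self.body):
            gb = layer.backward(gb, guided=guided)
        gs = g
        if self.shortcut is not None:
            for layer in reversed(self.shortcut):
                gs = layer.backward(gs, guided=guided)
        return gb + gs

    def zero_grad(self) -> None:
        for layer in self.iter_layers():
            if layer is not self:
                layer.zero_grad()

    def iter_layers(self):
        yield self
        for layer in self.body:
            yield from layer.iter_layers()
        if self.shortcut is not None:
            for layer in self.shortcut:
                yield from layer.iter_layers()
        yield self.post
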