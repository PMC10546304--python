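"""Minimal numpy neural-network layers with explicit backprop.

Layers store parameters in ``self.params`` and accumulate gradients in
``self.grads``; :class:`Sequential` chains them. :class:`Adam` updates any
collection of ``(layer, name)`` parameter references. Everything is pure
numpy and deterministic given the initialisation RNG, which is what makes
bitwise-reproducible training runs possible.

Array layout is ``(B, C, H, W)`` for images and ``(B, F)`` for vectors.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ValidationError

ParamRef = tuple["Layer", str]


class Layer:
    """Base layer; parameter-free layers keep empty param/grad dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def zero_grad(self) -> None:
        for k, v in self.params.items():
            self.grads[k] = np.zeros_like(v)


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _im2col(x: np.ndarray, k: int, stride: int) -> tuple[np.ndarray, int, int]:
    """(B, C, H, W) -> (B, Ho*Wo, C*k*k) patch matrix."""
    b, c, h, w = x.shape
    view = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = view.shape[2], view.shape[3]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(b, ho * wo, c * k * k)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, x_shape, k: int, stride: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    b, c, h, w = x_shape
    dx = np.zeros(x_shape, dtype=dcols.dtype)
    d = dcols.reshape(b, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += d[
                :, :, :, :, i, j
            ]
    return dx


class Conv2d(Layer):
    def __init__(self, in_ch: int, out_ch: int, k: int, stride: int = 1, pad: int = 0,
                 *, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_ch, self.out_ch, self.k, self.stride, self.pad = in_ch, out_ch, k, stride, pad
        self.params["W"] = _he_init(rng, (out_ch, in_ch * k * k), in_ch * k * k)
        self.params["b"] = np.zeros(out_ch, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.in_ch:
            raise ValidationError(f"Conv2d expected (B,{self.in_ch},H,W), got {x.shape}")
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        self._x_shape = x.shape
        cols, ho, wo = _im2col(x, self.k, self.stride)
        self._cols, self._ho, self._wo = cols, ho, wo
        y = cols @ self.params["W"].T + self.params["b"]
        return y.transpose(0, 2, 1).reshape(x.shape[0], self.out_ch, ho, wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b = dy.shape[0]
        dyf = dy.reshape(b, self.out_ch, -1).transpose(0, 2, 1)  # (B, L, out)
        self.grads["W"] += np.einsum("blo,blc->oc", dyf, self._cols, optimize=True)
        self.grads["b"] += dyf.sum(axis=(0, 1))
        dcols = dyf @ self.params["W"]
        dxp = _col2im(dcols, self._x_shape, self.k, self.stride, self._ho, self._wo)
        if self.pad:
            dxp = dxp[:, :, self.pad : -self.pad or None, self.pad : -self.pad or None]
        return dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(dy.dtype)


class MaxPool2d(Layer):
    def __init__(self, k: int, stride: Optional[int] = None) -> None:
        super().__init__()
        self.k, self.stride = k, stride if stride is not None else k

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        view = sliding_window_view(x, (self.k, self.k), axis=(2, 3))[:, :, ::self.stride, ::self.stride]
        ho, wo = view.shape[2], view.shape[3]
        flat = view.reshape(b, c, ho, wo, self.k * self.k)
        self._argmax = flat.argmax(axis=-1)
        self._x_shape, self._ho, self._wo = x.shape, ho, wo
        return np.take_along_axis(flat, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        ho, wo = self._ho, self._wo
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        bi, ci, hi, wi = np.indices((b, c, ho, wo), sparse=False)
        rows = hi * self.stride + self._argmax // self.k
        cols = wi * self.stride + self._argmax % self.k
        np.add.at(dx, (bi, ci, rows, cols), dy)
        return dx


class AvgPool2d(Layer):
    """Non-overlapping average pooling (stride = kernel)."""

    def __init__(self, k: int) -> None:
        super().__init__()
        self.k = k

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.k
        self._x_shape = x.shape
        return x[:, :, : h - h % k, : w - w % k].reshape(
            b, c, h // k, k, w // k, k
        ).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        k = self.k
        dx = np.zeros(self._x_shape, dtype=dy.dtype)
        up = np.repeat(np.repeat(dy, k, axis=2), k, axis=3) / (k * k)
        dx[:, :, : up.shape[2], : up.shape[3]] = up
        return dx


class GlobalAvgPool(Layer):
    """(B, C, H, W) -> (B, C)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._x_shape
        return np.broadcast_to(dy[:, :, None, None], self._x_shape).astype(dy.dtype) / (h * w)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator) -> None:
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.params["W"] = _he_init(rng, (n_out, n_in), n_in)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2 or x.shape[1] != self.n_in:
            raise ValidationError(f"Linear expected (B,{self.n_in}), got {x.shape}")
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    def param_refs(self) -> list[ParamRef]:
        refs: list[ParamRef] = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                refs.extend(layer.param_refs())
            else:
                refs.extend((layer, name) for name in layer.params)
        return refs


class Adam:
    """Adam optimizer over explicit parameter references."""

    def __init__(self, refs: Iterable[ParamRef], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.refs = list(refs)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.refs]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.refs]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, (layer, name) in enumerate(self.refs):
            g = layer.grads[name]
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            layer.params[name] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                layer.params[name].dtype
            )

    def zero_grad(self) -> None:
        for layer, _ in self.refs:
            layer.zero_grad()


class SGD:
    """Plain gradient descent (no momentum)."""

    def __init__(self, refs: Iterable[ParamRef], lr: float = 1e-2) -> None:
        self.refs = list(refs)
        self.lr = lr

    def step(self) -> None:
        for layer, name in self.refs:
            layer.params[name] -= (self.lr * layer.grads[name]).astype(
                layer.params[name].dtype
            )

    def zero_grad(self) -> None:
        for layer, _ in self.refs:
            layer.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_from_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean two-class cross-entropy and its gradient w.r.t. the logits.

    ``y`` holds integer class indices. The returned gradient is already
    divided by the batch size.
    """
    b = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.clip(p[np.arange(b), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(b), y] -= 1.0
    return loss, (grad / b).astype(np.float32)
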