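"""Minimal neural-network primitives in numpy with hand-written backpropagation.

Layers follow an NHWC layout and keep their forward cache between ``forward``
and ``backward`` calls. Gradient correctness is established by the
finite-difference tests; nothing here is stochastic, so forward passes are
bit-reproducible for fixed parameters.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import InputError

__all__ = [
    "softmax", "cross_entropy", "cross_entropy_grad",
    "Dense", "Conv2d", "MaxPool2", "Upsample2", "LeakyReLU", "GlobalAveragePool",
    "sgd_step",
]

EPS = 1e-12  # probability clip before log


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (shift-invariant via max subtraction)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise InputError("softmax of an empty array")
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def cross_entropy(probs: np.ndarray, labels: np.ndarray, reduction: str = "mean") -> float:
    """Cross-entropy -sum(y log p) over 2-class one-hot labels.

    ``probs`` has shape (..., 2) with the positive class last; ``labels`` is
    the matching integer/bool array. ``reduction="sum"`` is the literal summed
    loss; ``"mean"`` divides by the number of samples (training default).
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if probs.shape[:-1] != labels.shape:
        raise InputError(f"probs shape {probs.shape} does not match labels {labels.shape}")
    p_true = np.take_along_axis(probs, labels[..., None], axis=-1)[..., 0]
    losses = -np.log(np.clip(p_true, EPS, 1.0))
    if reduction == "sum":
        return float(losses.sum())
    if reduction == "mean":
        return float(losses.mean())
    raise InputError(f"unknown reduction {reduction!r}")


def cross_entropy_grad(probs: np.ndarray, labels: np.ndarray,
                       reduction: str = "mean") -> np.ndarray:
    """Gradient of :func:`cross_entropy` w.r.t. the *logits* that produced
    ``probs`` through a softmax: (p - y), scaled by the reduction."""
    labels = np.asarray(labels).astype(int)
    onehot = np.zeros_like(probs)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    g = probs - onehot
    if reduction == "mean":
        g = g / labels.size
    return g


class Layer:
    """Base: subclasses expose params() / grads() as name->array dicts."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.normal(0.0, scale, size=(d_in, d_out))).astype(dtype)
        self.b = np.zeros(d_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] != self.W.shape[0]:
            raise InputError(f"Dense expects {self.W.shape[0]} features, got {x.shape[-1]}")
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


def _conv2d_same(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Stride-1 'same' 2-D correlation; x is NHWC, W is (kh, kw, Cin, Cout)."""
    kh, kw, cin, cout = W.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    # windows: (N, H, W, Cin, kh, kw) -> flatten patch dims to match W flattening
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
    n, h, w = win.shape[:3]
    patches = win.transpose(0, 1, 2, 4, 5, 3).reshape(n, h, w, kh * kw * cin)
    Wf = W.reshape(kh * kw * cin, cout)
    return patches @ Wf


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, NHWC."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float32) -> None:
        scale = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.W = rng.normal(0.0, scale, size=(kernel, kernel, c_in, c_out)).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 4 or x.shape[-1] != self.W.shape[2]:
            raise InputError(
                f"Conv2d expects NHWC input with {self.W.shape[2]} channels, got {x.shape}")
        self._x = x
        return _conv2d_same(x, self.W) + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kh, kw, cin, cout = self.W.shape
        ph, pw = kh // 2, kw // 2
        xp = np.pad(self._x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        win = sliding_window_view(xp, (kh, kw), axis=(1, 2))
        n, h, w = win.shape[:3]
        patches = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, kh * kw * cin)
        self.dW[...] = (patches.T @ dout.reshape(n * h * w, cout)).reshape(self.W.shape)
        self.db[...] = dout.sum(axis=(0, 1, 2))
        # dx: full convolution of dout with the spatially flipped, io-swapped kernel
        W_back = self.W[::-1, ::-1].transpose(0, 1, 3, 2)
        return _conv2d_same(dout, W_back)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise InputError(f"MaxPool2 requires even spatial dims, got {x.shape}")
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = blocks.reshape(n, h // 2, w // 2, c, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        flat = np.zeros((n, h // 2, w // 2, c, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self._idx[..., None], dout[..., None], axis=-1)
        blocks = flat.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return blocks.reshape(n, h, w, c)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01) -> None:
        self.slope = slope

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class GlobalAveragePool(Layer):
    """NHWC -> NC mean over the spatial dims."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(dout.dtype)


def sgd_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             lr: float, momentum: float = 0.0,
             velocity: dict[str, np.ndarray] | None = None) -> None:
    """In-place SGD update, optionally with classical momentum.

    ``velocity`` holds the running update direction and is mutated in place;
    with ``momentum=0`` (or no velocity dict) this is plain gradient descent,
    and the first momentum step from a fresh velocity equals the plain step.
    """
    for name, p in params.items():
        g = grads[name]
        if momentum != 0.0 and velocity is not None:
            v = velocity.get(name)
            if v is None:
                v = np.zeros_like(p)
            v *= momentum
            v += g
            velocity[name] = v
            g = v
        p -= (lr * g).astype(p.dtype)
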