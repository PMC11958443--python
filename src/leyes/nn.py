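"""Minimal CPU neural-network engine for the desk-scale training demos.

A small, dependency-free stack of layers (3x3 same-padding convolutions via
im2col, ReLU, 2x2 max pooling, dense layers) with reverse-mode gradients and
an Adam optimizer.  Tensors are NHWC float32.  This is deliberately tiny: it
exists to train the demo center-regression CNN on streamed synthetic images
on a single CPU, not to be a general deep-learning framework.

Loss functions used by the training configurations (MSE/MAE for center
regression; binary cross-entropy, Dice, and focal losses for heatmap
models, with an optional BCE weight) live here as plain functions of
probabilities/targets.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "mse_loss",
    "mae_loss",
    "bce_loss",
    "dice_loss",
    "focal_loss",
    "combined_segmentation_loss",
]

_EPS = 1e-7


class Layer:
    """Base layer: forward/backward plus optional parameters."""

    trainable = True

    @property
    def params(self) -> list[np.ndarray]:
        return []

    @property
    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or kxk) same-padding convolution, NHWC, stride 1, He init."""

    def __init__(self, c_in: int, c_out: int, k: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        if k % 2 != 1:
            raise ValueError("kernel size must be odd (same padding)")
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        self.W = (rng.standard_normal((fan_in, c_out)) *
                  np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
        # (N, H, W, C, k, k) -> (N, H, W, k, k, C)
        win = win.transpose(0, 1, 2, 4, 5, 3)
        n, h, w = x.shape[:3]
        return np.ascontiguousarray(win).reshape(n * h * w, k * k * self.c_in)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        n, h, w, _ = x.shape
        out = self._cols @ self.W + self.b
        return out.reshape(n, h, w, self.c_out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, _ = self._shape
        g = grad.reshape(n * h * w, self.c_out).astype(np.float32)
        self.dW[...] = self._cols.T @ g
        self.db[...] = g.sum(axis=0)
        dcols = (g @ self.W.T).reshape(n, h, w, self.k, self.k, self.c_in)
        k, p = self.k, self.k // 2
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, self.c_in), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p : p + h, p : p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32)


class MaxPool2(Layer):
    """2x2 max pooling with stride 2 (input H, W must be even)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2 requires even spatial dimensions")
        v = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = v.max(axis=(2, 4))
        self._x = x
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = self._x.shape
        up = np.repeat(np.repeat(self._out, 2, axis=1), 2, axis=2)
        mask = self._x == up
        gup = np.repeat(np.repeat(grad, 2, axis=1), 2, axis=2)
        return np.where(mask, gup, 0.0).astype(np.float32)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        rng = rng or np.random.default_rng()
        self.W = (rng.standard_normal((n_in, n_out)) *
                  np.sqrt(2.0 / n_in)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    @property
    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(np.float32)
        self.dW[...] = self._x.T @ grad
        self.db[...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential:
    """A plain layer stack with forward/backward and weight snapshots."""

    def __init__(self, layers: Iterable[Layer]) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def parameters(self) -> list[tuple[Layer, np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            for p, g in zip(layer.params, layer.grads):
                out.append((layer, p, g))
        return out

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for _, p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (_, p, _), w in zip(self.parameters(), weights):
            p[...] = w

    def set_frozen(self, layer_indices: Iterable[int]) -> None:
        """Mark layers (by index into ``layers``) as frozen; others train."""
        frozen = set(layer_indices)
        for i, layer in enumerate(self.layers):
            layer.trainable = i not in frozen


class Adam:
    """Adam with per-step bias correction; skips frozen layers."""

    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in model.parameters()]
        self.v = [np.zeros_like(p) for _, p, _ in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, p, g) in enumerate(self.model.parameters()):
            if not layer.trainable:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# losses (value, gradient w.r.t. prediction)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def bce_loss(p: np.ndarray, t: np.ndarray, weight: float = 1.0) -> float:
    """Binary cross-entropy on probabilities, positive class scaled by
    ``weight`` (a weight above 1 counters the sparse-foreground imbalance of
    feature heatmaps)."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(weight * t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))


def dice_loss(p: np.ndarray, t: np.ndarray) -> float:
    """1 - Dice overlap coefficient (soft, on probabilities)."""
    num = 2.0 * np.sum(p * t) + _EPS
    den = np.sum(p) + np.sum(t) + _EPS
    return float(1.0 - num / den)


def focal_loss(p: np.ndarray, t: np.ndarray, gamma: float = 2.0) -> float:
    """Focal loss: cross-entropy down-weighted for well-classified pixels."""
    p = np.clip(p, _EPS, 1.0 - _EPS)
    pt = np.where(t > 0.5, p, 1.0 - p)
    return float(-np.mean((1.0 - pt) ** gamma * np.log(pt)))


def combined_segmentation_loss(
    p: np.ndarray, t: np.ndarray, bce_weight: float = 1.0,
    gamma: float = 2.0,
) -> float:
    """BCE + Dice + focal, the loss family used for the heatmap/U-Net
    training configurations."""
    return (bce_loss(p, t, weight=bce_weight) + dice_loss(p, t)
            + focal_loss(p, t, gamma=gamma))
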