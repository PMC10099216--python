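"""Minimal feed-forward neural-network engine (numpy).

Implements exactly what the classifier stack needs: 2-D convolution
(im2col), max pooling, dense layers, ReLU, softmax cross-entropy, plain
mini-batch SGD and validation-loss early stopping.  Layers store their
parameters and gradients; a :class:`Sequential` threads forward/backward
passes through them.  All randomness (initialisation, batch shuffling)
comes from explicitly passed :class:`numpy.random.Generator` objects, so
training is reproducible run to run on one machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "ReLU",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Sequential",
    "softmax",
    "cross_entropy",
    "train_network",
    "TrainingHistory",
]


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilised."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy  -Σ p(x) log q(x)  for one-hot truth p."""
    n = probs.shape[0]
    return float(-np.log(probs[np.arange(n), y] + 1e-12).mean())


class Layer:
    """Base class; stateless layers override forward/backward only."""

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        # He initialisation (ReLU networks)
        self.W = (rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)).astype(
            np.float32
        )
        self.b = np.zeros(n_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Conv2D(Layer):
    """3×3-style same-padding convolution over NCHW input via im2col."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
    ):
        fan_in = c_in * kernel * kernel
        self.W = (
            rng.standard_normal((c_out, fan_in)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out
        self.pad = kernel // 2

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        n, c, h, w = x.shape
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        n, c, h, w = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.W.T + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k = self.kernel
        g = grad.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.gW[...] = g.T @ self._cols
        self.gb[...] = g.sum(axis=0)
        gcols = (g @ self.W).reshape(n, h, w, c, k, k)
        # col2im: scatter-add each kernel offset back onto the padded grid
        gx = np.zeros((n, c, h + 2 * self.pad, w + 2 * self.pad), dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, self.pad : self.pad + h, self.pad : self.pad + w]

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.gW, self.gb]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; spatial dims must divide the pool size."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        q = self.size
        if h % q or w % q:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by pool {q}")
        self._shape = x.shape
        blocks = x.reshape(n, c, h // q, q, w // q, q).transpose(0, 1, 2, 4, 3, 5)
        flat = blocks.reshape(n, c, h // q, w // q, q * q)
        self._arg = flat.argmax(axis=-1)
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        q = self.size
        flat = np.zeros((n, c, h // q, w // q, q * q), dtype=grad.dtype)
        np.put_along_axis(flat, self._arg[..., None], grad[..., None], axis=-1)
        blocks = flat.reshape(n, c, h // q, w // q, q, q).transpose(0, 1, 2, 4, 3, 5)
        return blocks.reshape(n, c, h, w)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential:
    """A feed-forward stack trained with softmax cross-entropy."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [
            softmax(self.forward(x[i : i + batch_size]))
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(out, axis=0)

    def loss(self, x: np.ndarray, y: np.ndarray, batch_size: int = 256) -> float:
        total, n = 0.0, x.shape[0]
        for i in range(0, n, batch_size):
            probs = softmax(self.forward(x[i : i + batch_size]))
            total += cross_entropy(probs, y[i : i + batch_size]) * probs.shape[0]
        return total / n

    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float) -> float:
        logits = self.forward(x)
        probs = softmax(logits)
        loss = cross_entropy(probs, y)
        grad = probs.copy()
        grad[np.arange(x.shape[0]), y] -= 1.0
        grad /= x.shape[0]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for layer in self.layers:
            for p, g in zip(layer.params(), layer.grads()):
                p -= lr * g
        return loss

    # -- weight (de)serialisation ------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p in layer.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p in layer.params()]
        if len(flat) != len(weights):
            raise ValueError(
                f"weight count mismatch: model has {len(flat)}, got {len(weights)}"
            )
        for p, w in zip(flat, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w

    def layer_census(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for layer in self.layers:
            name = type(layer).__name__
            counts[name] = counts.get(name, 0) + 1
        return counts


@dataclass
class TrainingHistory:
    """Per-epoch losses plus where (and why) training stopped."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    early_stopped: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def train_network(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    learning_rate: float,
    batch_size: int,
    max_epochs: int,
    patience: int,
    rng: np.random.Generator,
) -> TrainingHistory:
    """Mini-batch SGD on cross-entropy with validation-loss early stopping.

    Stops when the validation loss has failed to improve for ``patience``
    consecutive epochs (or at ``max_epochs``); the best-validation weights
    are restored before returning.
    """
    history = TrainingHistory()
    n = x_train.shape[0]
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(n)
        running, seen = 0.0, 0
        for i in range(0, n, batch_size):
            idx = order[i : i + batch_size]
            loss = model.train_step(x_train[idx], y_train[idx], learning_rate)
            running += loss * idx.size
            seen += idx.size
        val = model.loss(x_val, y_val)
        history.train_loss.append(running / seen)
        history.val_loss.append(val)
        history.stopped_epoch = epoch
        if val < best_val - 1e-9:
            best_val = val
            best_weights = model.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                history.early_stopped = True
                break
    model.set_weights(best_weights)
    return history
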