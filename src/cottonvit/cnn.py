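"""A small 1-D convolutional network for spectral regression, in numpy.

Architecture: conv(64 kernels) -> avg-pool(2) -> conv(128 kernels) ->
avg-pool(2) -> flatten -> fc(256) -> fc(1), ReLU activations, trained
with plain SGD on the mean-squared-error loss, batch size 4.  Inputs
are short feature vectors (selected wavelengths and/or texture
features), so the whole network is a few hundred kilobytes of weights
and trains in seconds on a CPU.

Inputs and targets are standardized internally with training-set
statistics (the SGD step size of 1e-4 assumes unit-scale data);
predictions are mapped back to the original target units.  All
randomness (initialization, epoch shuffling) flows from one seed, so
training is bit-reproducible on a single machine.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _conv1d_same(x: np.ndarray, W: np.ndarray, bias: np.ndarray | None) -> np.ndarray:
    """x: (B, C, L), W: (F, C, K) odd K, same padding -> (B, F, L)."""
    K = W.shape[2]
    pad = K // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, K, axis=2)       # (B, C, L, K)
    out = np.einsum("bclk,fck->bfl", win, W, optimize=True)
    if bias is not None:
        out += bias[None, :, None]
    return out


class _Conv1d:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)

    def forward(self, x):
        self._x = x
        return _conv1d_same(x, self.W, self.b)

    def backward(self, dy):
        K = self.W.shape[2]
        pad = K // 2
        xp = np.pad(self._x, ((0, 0), (0, 0), (pad, pad)))
        win = sliding_window_view(xp, K, axis=2)
        self.dW = np.einsum("bfl,bclk->fck", dy, win, optimize=True)
        self.db = dy.sum(axis=(0, 2))
        # dx = "full" correlation of dy with the flipped, transposed kernel
        Wt = self.W.transpose(1, 0, 2)[:, :, ::-1]
        return _conv1d_same(dy, Wt, None)

    def step(self, lr):
        self.W -= lr * self.dW
        self.b -= lr * self.db


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, dy):
        return dy * self._m


class _AvgPool2:
    def forward(self, x):
        B, C, L = x.shape
        self._L = L
        Lh = L // 2
        return x[:, :, : 2 * Lh].reshape(B, C, Lh, 2).mean(axis=3)

    def backward(self, dy):
        B, C, Lh = dy.shape
        dx = np.zeros((B, C, self._L))
        up = np.repeat(dy, 2, axis=2) / 2.0
        dx[:, :, : 2 * Lh] = up
        return dx


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def step(self, lr):
        self.W -= lr * self.dW
        self.b -= lr * self.db


class Conv1dRegressor:
    """Two-conv / two-pool / two-dense 1-D CNN regressor."""

    def __init__(self, conv1_filters: int = 64, conv2_filters: int = 128,
                 kernel_size: int = 3, fc_units: int = 256, lr: float = 1e-4,
                 epochs: int = 50, batch_size: int = 4, rng_seed: int = 0):
        self.conv1_filters = conv1_filters
        self.conv2_filters = conv2_filters
        self.kernel_size = kernel_size
        self.fc_units = fc_units
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.rng_seed = rng_seed
        self.loss_curve_: list[float] = []

    # -- internals ---------------------------------------------------------
    def _build(self, n_features: int, rng: np.random.Generator) -> None:
        if n_features < 4:
            raise ValueError(
                f"input length {n_features} shorter than the receptive field "
                "(two pool-2 stages need at least 4 points)")
        self.c1 = _Conv1d(1, self.conv1_filters, self.kernel_size, rng)
        self.r1 = _ReLU()
        self.p1 = _AvgPool2()
        self.c2 = _Conv1d(self.conv1_filters, self.conv2_filters, self.kernel_size, rng)
        self.r2 = _ReLU()
        self.p2 = _AvgPool2()
        flat = self.conv2_filters * (n_features // 2 // 2)
        self.f1 = _Linear(flat, self.fc_units, rng)
        self.r3 = _ReLU()
        self.f2 = _Linear(self.fc_units, 1, rng)
        self._layers = [self.c1, self.r1, self.p1, self.c2, self.r2, self.p2]

    def _forward(self, xb: np.ndarray) -> np.ndarray:
        h = xb[:, None, :]
        for layer in self._layers:
            h = layer.forward(h)
        self._pre_flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.r3.forward(self.f1.forward(h))
        return self.f2.forward(h)

    def _backward(self, dloss: np.ndarray) -> None:
        d = self.f2.backward(dloss)
        d = self.f1.backward(self.r3.backward(d))
        d = d.reshape(self._pre_flat_shape)
        for layer in reversed(self._layers):
            d = layer.backward(d)

    def _step(self) -> None:
        for layer in (self.c1, self.c2, self.f1, self.f2):
            layer.step(self.lr)

    # -- public API --------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "Conv1dRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        rng = np.random.default_rng(self.rng_seed)
        self._x_mean = X.mean(axis=0)
        self._x_sd = X.std(axis=0, ddof=1)
        self._x_sd[self._x_sd == 0] = 1.0
        self._y_mean = y.mean()
        self._y_sd = y.std(ddof=1) or 1.0
        Xs = (X - self._x_mean) / self._x_sd
        ys = (y - self._y_mean) / self._y_sd

        self._build(X.shape[1], rng)
        n = X.shape[0]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = self._forward(Xs[idx]).ravel()
                err = pred - ys[idx]
                losses.append(float(np.mean(err ** 2)))
                self._backward((2.0 * err / err.size)[:, None])
                self._step()
            self.loss_curve_.append(float(np.mean(losses)))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self._x_mean) / self._x_sd
        out = self._forward(Xs).ravel()
        return out * self._y_sd + self._y_mean


def mse(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Mean squared error, sum((yhat - y)^2) / n."""
    y_pred = np.asarray(y_pred, float).ravel()
    y_true = np.asarray(y_true, float).ravel()
    return float(np.mean((y_pred - y_true) ** 2))
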