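"""Minimal 1D convolutional network stack in numpy.

Implements exactly the pieces the gaze-direction models need — Conv1D
(same padding, stride 1), batch normalization, ReLU, max pooling, dropout,
dense layers, residual blocks with optional 1x1 projection, a sigmoid
head, binary cross-entropy, and Adam — with hand-written backprop.
Everything is deterministic given the training seed.

Array convention: activations are ``(N, L, C)`` (batch, length, channels);
dense layers take ``(N, D)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base layer: ``params()`` yields (array, grad, apply_l2) triples."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _, _ in self.params())


class Conv1D(Layer):
    """Stride-1 'same' 1D convolution.

    Weights ``(kernel, in_ch, out_ch)``, He-initialized.  ``l2`` marks the
    kernel (and bias, matching an L2 weight-and-bias regularizer) for
    weight decay in the optimizer.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, l2: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.w = rng.normal(0.0, scale, size=(kernel, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.kernel = kernel
        self.l2 = l2

    def forward(self, x, train):
        k = self.kernel
        pl, pr = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # windows: (N, L, k, C_in)
        win = sliding_window_view(xp, k, axis=1).transpose(0, 1, 3, 2)
        self._win = win
        self._xshape = x.shape
        return np.tensordot(win, self.w, axes=([2, 3], [0, 1])) + self.b

    def backward(self, dout):
        k = self.kernel
        pl, pr = (k - 1) // 2, k // 2
        self.dw += np.tensordot(self._win, dout, axes=([0, 1], [0, 1]))
        self.db += dout.sum(axis=(0, 1))
        n, L, _ = self._xshape
        dxp = np.zeros((n, L + pl + pr, self.w.shape[1]))
        # scatter each kernel tap back onto the padded input
        for j in range(k):
            dxp[:, j : j + L, :] += np.tensordot(dout, self.w[j], axes=([2], [1]))
        return dxp[:, pl : pl + L, :]

    def params(self):
        return [(self.w, self.dw, self.l2), (self.b, self.db, self.l2)]


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, l2: bool = True,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self.l2 = l2

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [(self.w, self.dw, self.l2), (self.b, self.db, self.l2)]


class BatchNorm(Layer):
    """Per-channel batch normalization over all non-channel axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._train = train
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes = self._axes
        self.dgamma += (dout * self._xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        dxhat = dout * self.gamma
        if not self._train:  # running stats are constants w.r.t. the input
            return dxhat * self._inv_std
        m = self._m
        return (
            self._inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes)
                - self._xhat * (dxhat * self._xhat).sum(axis=axes)
            )
        )

    def params(self):
        return [(self.gamma, self.dgamma, False), (self.beta, self.dbeta, False)]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling; a trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train):
        n, L, c = x.shape
        lo = L // self.pool
        xt = x[:, : lo * self.pool, :].reshape(n, lo, self.pool, c)
        self._arg = xt.argmax(axis=2)
        self._xshape = x.shape
        return xt.max(axis=2)

    def backward(self, dout):
        n, lo, c = dout.shape
        dx = np.zeros(self._xshape)
        dxt = dx[:, : lo * self.pool, :].reshape(n, lo, self.pool, c)
        ni, li, ci = np.ogrid[:n, :lo, :c]
        dxt[ni, li, self._arg, ci] = dout
        return dx


class Dropout(Layer):
    """Inverted dropout; the mask RNG is supplied by the trainer."""

    def __init__(self, p: float = 0.2):
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, train):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Sigmoid(Layer):
    def forward(self, x, train):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Residual(Layer):
    """A residual unit: ``relu(body(x) + shortcut(x))``.

    The shortcut is the identity when channel counts match, else a 1x1
    projection convolution (with its own batchnorm).
    """

    def __init__(self, body: list[Layer], in_ch: int, out_ch: int,
                 rng: np.random.Generator | None = None, l2: bool = True):
        self.body = body
        if in_ch == out_ch:
            self.shortcut: list[Layer] = []
        else:
            self.shortcut = [
                Conv1D(in_ch, out_ch, kernel=1, l2=l2, rng=rng),
                BatchNorm(out_ch),
            ]
        self.relu = ReLU()

    def forward(self, x, train):
        h = x
        for layer in self.body:
            h = layer.forward(h, train)
        s = x
        for layer in self.shortcut:
            s = layer.forward(s, train)
        return self.relu.forward(h + s, train)

    def backward(self, dout):
        d = self.relu.backward(dout)
        ds = d
        for layer in reversed(self.shortcut):
            ds = layer.backward(ds)
        dh = d
        for layer in reversed(self.body):
            dh = layer.backward(dh)
        return dh + ds

    def params(self):
        out = []
        for layer in self.body + self.shortcut:
            out.extend(layer.params())
        return out


class Model:
    """A feed-forward stack ending in a :class:`Sigmoid` head."""

    def __init__(self, layers: list[Layer], name: str = "model"):
        assert isinstance(layers[-1], Sigmoid)
        self.layers = layers
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def forward_logits(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers[:-1]:
            x = layer.forward(x, train)
        return x

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers[:-1]):
            d = layer.backward(d)

    def predict_proba(self, x: np.ndarray, batch: int = 1024) -> np.ndarray:
        out = [self.forward(x[i : i + batch], train=False) for i in range(0, len(x), batch)]
        return np.concatenate(out).ravel() if out else np.empty(0)

    def predict(self, x: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(x) >= threshold).astype(int)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(p.size for p, _, _ in self.params())

    def zero_grad(self) -> None:
        for _, g, _ in self.params():
            g[...] = 0.0

    def seed_dropout(self, rng: np.random.Generator) -> None:
        stack = list(self.layers)
        while stack:
            layer = stack.pop()
            if isinstance(layer, Dropout):
                layer.rng = rng
            if isinstance(layer, Residual):
                stack.extend(layer.body + layer.shortcut)


class Adam:
    """Adam with L2 weight decay added to marked parameters' gradients."""

    def __init__(self, params, lr: float = 1e-3, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.entries = params
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _, _ in params]
        self.v = [np.zeros_like(p) for p, _, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g, use_l2) in enumerate(self.entries):
            grad = g + (2.0 * self.l2 * p if use_l2 and self.l2 else 0.0)
            self.m[i] = b1 * self.m[i] + (1 - b1) * grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * grad * grad
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def binary_cross_entropy(p: np.ndarray, y: np.ndarray, eps: float = 1e-7) -> float:
    p = np.clip(p.ravel(), eps, 1 - eps)
    y = y.ravel()
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
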