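"""Minimal numpy neural-network kit.

Implements exactly the layer vocabulary the apnea base classifiers need:
1-D convolution ("same" padding), batch normalisation, max pooling,
dropout, dense layers, an LSTM, and a time-distributed wrapper, trained
with Adam on a softmax cross-entropy loss.  Forward and backward passes
are hand-derived and covered by numeric gradient checks in the test
suite.  Everything is plain float64 numpy, so results are bit-reproducible
for a fixed seed on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "ReLU",
    "Conv1D",
    "BatchNorm",
    "MaxPool1D",
    "Dropout",
    "Flatten",
    "Reshape",
    "LSTM",
    "TimeDistributed",
    "Sequential",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-shift stabilisation."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy of integer targets ``y`` under softmax(logits).

    Returns ``(loss, grad)`` where ``grad`` is d(loss)/d(logits).
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = float(-np.log(p[np.arange(n), y] + eps).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Layer:
    """Base layer: parameter dict + cached forward state for backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sublayers(self):
        return []


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        # He initialisation; all dense layers here feed ReLU or softmax
        scale = np.sqrt(2.0 / in_dim)
        self.params["W"] = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.params["b"] = np.zeros(out_dim)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, g):
        self.grads["W"] = self._x.T @ g
        self.grads["b"] = g.sum(axis=0)
        return g @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Conv1D(Layer):
    """1-D convolution over (N, L, C) with stride 1 and "same" padding."""

    def __init__(self, in_ch: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.kernel = kernel
        scale = np.sqrt(2.0 / (kernel * in_ch))
        self.params["W"] = rng.normal(0.0, scale, size=(kernel, in_ch, filters))
        self.params["b"] = np.zeros(filters)

    def forward(self, x, train):
        n, L, c = x.shape
        k = self.kernel
        pl = (k - 1) // 2
        pr = k - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # (N, L, k, C) view of all receptive fields
        windows = np.stack([xp[:, j : j + L, :] for j in range(k)], axis=2)
        self._windows = windows
        self._in_shape = (n, L, c, pl)
        return np.tensordot(windows, self.params["W"], axes=([2, 3], [0, 1])) + self.params["b"]

    def backward(self, g):
        n, L, c, pl = self._in_shape
        k = self.kernel
        self.grads["W"] = np.tensordot(self._windows, g, axes=([0, 1], [0, 1]))
        self.grads["b"] = g.sum(axis=(0, 1))
        dxp = np.zeros((n, L + k - 1, c))
        W = self.params["W"]
        for j in range(k):
            dxp[:, j : j + L, :] += g @ W[j].T
        return dxp[:, pl : pl + L, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation over (N, L, C) or (N, C)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, axes, x.size // x.shape[-1], train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, g):
        xhat, inv, axes, m, train = self._cache
        self.grads["gamma"] = (g * xhat).sum(axis=axes)
        self.grads["beta"] = g.sum(axis=axes)
        gamma = self.params["gamma"]
        if not train:
            return g * gamma * inv
        gsum = g.sum(axis=axes)
        gx = (g * xhat).sum(axis=axes)
        return (gamma * inv / m) * (m * g - gsum - xhat * gx)


class MaxPool1D(Layer):
    """Non-overlapping max pooling of size 2 over the length axis of (N, L, C)."""

    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        n, L, c = x.shape
        s = self.size
        L2 = L // s
        xr = x[:, : L2 * s, :].reshape(n, L2, s, c)
        self._arg = xr.argmax(axis=2)
        self._in_shape = (n, L, c)
        return xr.max(axis=2)

    def backward(self, g):
        n, L, c = self._in_shape
        s = self.size
        L2 = L // s
        dxr = np.zeros((n, L2, s, c))
        np.put_along_axis(dxr, self._arg[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros((n, L, c))
        dx[:, : L2 * s, :] = dxr.reshape(n, L2 * s, c)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...]):
        super().__init__()
        self.target = target

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, g):
        return g.reshape(self._shape)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTM(Layer):
    """Single-layer LSTM over (N, T, D); emits the final hidden state (N, H).

    Gate order in the fused weight matrices is input, forget, cell, output;
    the forget-gate bias starts at 1 (standard long-memory initialisation).
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        scale_x = np.sqrt(1.0 / in_dim)
        scale_h = np.sqrt(1.0 / hidden)
        self.params["Wx"] = rng.normal(0.0, scale_x, size=(in_dim, 4 * hidden))
        self.params["Wh"] = rng.normal(0.0, scale_h, size=(hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0
        self.params["b"] = b

    def forward(self, x, train):
        n, T, d = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        self._caches = []
        self._x_shape = x.shape
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            self._caches.append((xt, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
        return h

    def backward(self, dh):
        n, T, d = self._x_shape
        H = self.hidden
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.zeros((n, T, d))
        dc = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new = self._caches[t]
            tc = np.tanh(c_new)
            do = dh * tc
            dc = dc + dh * o * (1 - tc**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            dWx += xt.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc_prev
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


class TimeDistributed(Layer):
    """Apply a sub-stack independently to each step of (N, T, ...)."""

    def __init__(self, layers: list[Layer]):
        super().__init__()
        self.layers = layers

    def sublayers(self):
        return self.layers

    def forward(self, x, train):
        n, T = x.shape[:2]
        self._nt = (n, T)
        out = x.reshape((n * T,) + x.shape[2:])
        for layer in self.layers:
            out = layer.forward(out, train)
        return out.reshape((n, T) + out.shape[1:])

    def backward(self, g):
        n, T = self._nt
        grad = g.reshape((n * T,) + g.shape[2:])
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad.reshape((n, T) + grad.shape[1:])


def _walk(layers):
    for layer in layers:
        yield layer
        yield from _walk(layer.sublayers())


class Sequential:
    """A feed-forward stack with softmax cross-entropy training via Adam."""

    def __init__(self, layers: list[Layer], seed: int = 0):
        self.layers = layers
        self.seed = seed
        self._adam_state: dict[tuple[int, str], tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    def all_layers(self):
        return list(_walk(self.layers))

    def n_params(self) -> int:
        return sum(p.size for l in self.all_layers() for p in l.params.values())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(x, dtype=float)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def _adam_step(self, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for layer in self.all_layers():
            for name, p in layer.params.items():
                g = layer.grads.get(name)
                if g is None:
                    continue
                key = (id(layer), name)
                if key not in self._adam_state:
                    self._adam_state[key] = (np.zeros_like(p), np.zeros_like(p))
                m, v = self._adam_state[key]
                m[:] = beta1 * m + (1 - beta1) * g
                v[:] = beta2 * v + (1 - beta2) * g**2
                mhat = m / (1 - beta1**t)
                vhat = v / (1 - beta2**t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 64,
        lr: float = 1e-3,
        rng: np.random.Generator | None = None,
    ) -> list[dict]:
        """Train with Adam; returns one ``{"loss", "accuracy"}`` entry per epoch."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        if rng is None:
            rng = np.random.default_rng(self.seed)
        n = x.shape[0]
        history: list[dict] = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.forward(x[idx], train=True)
                loss, grad = softmax_cross_entropy(logits, y[idx])
                self.backward(grad)
                self._adam_step(lr)
                losses.append(loss * len(idx))
                correct += int((logits.argmax(axis=1) == y[idx]).sum())
            history.append({"loss": float(np.sum(losses) / n), "accuracy": correct / n})
        return history

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = []
        for start in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[start : start + batch_size], train=False)))
        return np.concatenate(out, axis=0) if out else np.zeros((0, 2))
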