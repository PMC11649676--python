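"""Minimal seeded neural-network layer library.

Just enough machinery for the four small epoch classifiers: dense,
2-D convolution (stride 1, valid padding), max pooling (stride = pool size),
flatten and a single LSTM layer, trained with Adam on binary cross-entropy.
Inputs are NHWC; gradients are exact (checked against finite differences in
the test suite). Initialization is Glorot-uniform from a caller-supplied
generator, so identical seeds give identical fits.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Dense", "Conv2D", "MaxPool2D", "Flatten", "LSTM", "Network",
           "Adam", "bce_loss"]


def _act(name):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(z.dtype)
    if name == "sigmoid":
        def f(z):
            return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
        return f, lambda z, a: a * (1.0 - a)
    if name == "tanh":
        return np.tanh, lambda z, a: 1.0 - a ** 2
    if name == "linear":
        return lambda z: z, lambda z, a: np.ones_like(z)
    raise ValueError(f"unknown activation {name!r}")


def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    trainable: tuple[str, ...] = ()

    def params(self):
        return [(self, name) for name in self.trainable]

    @property
    def n_params(self) -> int:
        return int(sum(getattr(self, n).size for n in self.trainable))


class Dense(Layer):
    trainable = ("W", "b")

    def __init__(self, n_in: int, units: int, activation: str, rng):
        self.units = units
        self.activation = activation
        self.W = _glorot(rng, (n_in, units), n_in, units)
        self.b = np.zeros(units)
        self._f, self._df = _act(activation)

    def forward(self, x):
        self._x = x
        self._z = x @ self.W + self.b
        self._a = self._f(self._z)
        return self._a

    def backward(self, grad):
        dz = grad * self._df(self._z, self._a)
        self.dW = self._x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T


class Conv2D(Layer):
    """Valid, stride-1 2-D convolution on NHWC input."""

    trainable = ("W", "b")

    def __init__(self, in_channels: int, filters: int,
                 kernel: tuple[int, int], activation: str, rng):
        kh, kw = kernel
        self.kernel = (kh, kw)
        self.filters = filters
        self.activation = activation
        fan_in = kh * kw * in_channels
        self.W = _glorot(rng, (kh, kw, in_channels, filters), fan_in,
                         filters)
        self.b = np.zeros(filters)
        self._f, self._df = _act(activation)

    def _cols(self, x):
        B, H, W, C = x.shape
        kh, kw = self.kernel
        Ho, Wo = H - kh + 1, W - kw + 1
        cols = np.empty((B, Ho, Wo, kh, kw, C), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, :, i, j, :] = x[:, i:i + Ho, j:j + Wo, :]
        return cols

    def forward(self, x):
        self._x_shape = x.shape
        self._cols_cache = self._cols(x)
        self._z = (
            np.tensordot(self._cols_cache, self.W, axes=([3, 4, 5],
                                                         [0, 1, 2]))
            + self.b
        )
        self._a = self._f(self._z)
        return self._a

    def backward(self, grad):
        dz = grad * self._df(self._z, self._a)
        self.dW = np.tensordot(self._cols_cache, dz,
                               axes=([0, 1, 2], [0, 1, 2]))
        self.db = dz.sum(axis=(0, 1, 2))
        B, H, W, C = self._x_shape
        kh, kw = self.kernel
        Ho, Wo = H - kh + 1, W - kw + 1
        grad_cols = np.tensordot(dz, self.W, axes=([3], [3]))
        # grad_cols: (B, Ho, Wo, kh, kw, C) -> scatter back
        gx = np.zeros(self._x_shape, dtype=grad.dtype)
        for i in range(kh):
            for j in range(kw):
                gx[:, i:i + Ho, j:j + Wo, :] += grad_cols[:, :, :, i, j, :]
        self._cols_cache = None
        return gx


class MaxPool2D(Layer):
    """Max pooling, stride equal to pool size, remainder cropped."""

    def __init__(self, pool: tuple[int, int]):
        self.pool = pool

    def forward(self, x):
        ph, pw = self.pool
        B, H, W, C = x.shape
        nh, nw = H // ph, W // pw
        xc = x[:, : nh * ph, : nw * pw, :]
        self._xr = xc.reshape(B, nh, ph, nw, pw, C)
        out = self._xr.max(axis=(2, 4))
        mask = self._xr == out[:, :, None, :, None, :]
        # split gradient evenly between tied maxima
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._in_shape = x.shape
        return out

    def backward(self, grad):
        B, H, W, C = self._in_shape
        ph, pw = self.pool
        nh, nw = H // ph, W // pw
        gx = np.zeros(self._in_shape, dtype=grad.dtype)
        spread = self._mask * grad[:, :, None, :, None, :]
        gx[:, : nh * ph, : nw * pw, :] = spread.reshape(
            B, nh * ph, nw * pw, C)
        return gx


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state.

    Accepts NHWC input from a convolutional block, treating the width axis
    as time and height x channels as features. ``activation`` overrides the
    candidate/output nonlinearity (the recurrent gates stay sigmoid).
    """

    trainable = ("Wx", "Wh", "b")

    def __init__(self, n_features: int, units: int, activation: str, rng):
        self.units = units
        self.activation = activation
        u = units
        self.Wx = _glorot(rng, (n_features, 4 * u), n_features, u)
        self.Wh = _glorot(rng, (u, 4 * u), u, u)
        self.b = np.zeros(4 * u)
        self._sig, self._dsig = _act("sigmoid")
        self._g, self._dg = _act(activation)

    def _as_sequence(self, x):
        if x.ndim == 4:  # (B, H, T, C) -> (B, T, H*C)
            B, H, T, C = x.shape
            return np.ascontiguousarray(
                x.transpose(0, 2, 1, 3)).reshape(B, T, H * C)
        return x

    def forward(self, x):
        self._in_shape = x.shape
        seq = self._as_sequence(x)
        B, T, F = seq.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._seq = seq
        self._cache = []
        for t in range(T):
            z = seq[:, t, :] @ self.Wx + h @ self.Wh + self.b
            zi, zf, zg, zo = (z[:, :u], z[:, u:2 * u],
                              z[:, 2 * u:3 * u], z[:, 3 * u:])
            i = self._sig(zi)
            f = self._sig(zf)
            g = self._g(zg)
            o = self._sig(zo)
            c_new = f * c + i * g
            ac = self._g(c_new)
            h_new = o * ac
            self._cache.append((h, c, i, f, g, o, c_new, ac, zg))
            h, c = h_new, c_new
        return h

    def backward(self, grad):
        seq = self._seq
        B, T, F = seq.shape
        u = self.units
        self.dWx = np.zeros_like(self.Wx)
        self.dWh = np.zeros_like(self.Wh)
        self.db = np.zeros_like(self.b)
        gseq = np.zeros_like(seq)
        dh = grad
        dc = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c_new, ac, zg = self._cache[t]
            do = dh * ac
            dc = dc + dh * o * self._dg(c_new, ac)
            di = dc * g
            df = dc * c_prev
            dg_ = dc * i
            dzi = di * i * (1 - i)
            dzf = df * f * (1 - f)
            dzg = dg_ * self._dg(zg, g)
            dzo = do * o * (1 - o)
            dz = np.concatenate([dzi, dzf, dzg, dzo], axis=1)
            self.dWx += seq[:, t, :].T @ dz
            self.dWh += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            gseq[:, t, :] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        self._cache = None
        if len(self._in_shape) == 4:
            B_, H, T_, C = self._in_shape
            return gseq.reshape(B_, T_, H, C).transpose(0, 2, 1, 3)
        return gseq


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state: dict = {}

    def step(self, params):
        self.t += 1
        for layer, name in params:
            g = getattr(layer, "d" + name)
            key = (id(layer), name)
            m, v = self.state.get(key, (np.zeros_like(g), np.zeros_like(g)))
            m = self.beta1 * m + (1 - self.beta1) * g
            v = self.beta2 * v + (1 - self.beta2) * g ** 2
            self.state[key] = (m, v)
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            w = getattr(layer, name)
            setattr(layer, name,
                    w - self.lr * mhat / (np.sqrt(vhat) + self.eps))


def bce_loss(p, y):
    p = np.clip(p, 1e-7, 1 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


class Network:
    """A plain layer stack with an Adam/BCE training loop."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x):
        return self.forward(x).ravel()

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    def get_weights(self):
        return [getattr(layer, n).copy() for layer, n in self.params()]

    def set_weights(self, weights):
        for (layer, n), w in zip(self.params(), weights):
            setattr(layer, n, w.copy())

    def _backward_from_proba(self, p, y):
        # combined d(BCE)/d(prob); the final sigmoid layer supplies p(1-p)
        p = np.clip(p, 1e-7, 1 - 1e-7)
        grad = ((p - y) / (p * (1 - p)) / len(y)).reshape(-1, 1)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def fit(self, X, y, X_val=None, y_val=None, max_epochs: int = 100,
            batch_size: int = 8, lr: float = 1e-3, patience: int = 10,
            rng: np.random.Generator | None = None):
        """Train with Adam on BCE; early-stop on validation loss.

        Returns a history dict. The weights kept are those of the best
        validation epoch (final weights if no validation data).
        """
        rng = rng or np.random.default_rng(0)
        opt = Adam(lr=lr)
        history = {"loss": [], "val_loss": []}
        best = (np.inf, None)
        wait = 0
        n = len(X)
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start: start + batch_size]
                p = self.forward(X[idx]).ravel()
                losses.append(bce_loss(p, y[idx]) * len(idx))
                self._backward_from_proba(p, y[idx])
                opt.step(self.params())
            epoch_loss = float(np.sum(losses) / n)
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}; last finite "
                    f"losses: {history['loss'][-3:]}")
            history["loss"].append(epoch_loss)
            if X_val is not None and len(X_val):
                val_loss = bce_loss(self.predict_proba(X_val), y_val)
                history["val_loss"].append(val_loss)
                if val_loss < best[0] - 1e-6:
                    best = (val_loss, self.get_weights())
                    wait = 0
                else:
                    wait += 1
                    if wait >= patience:
                        break
        if best[1] is not None:
            self.set_weights(best[1])
        return history
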