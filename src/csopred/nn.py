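"""A compact feed-forward/recurrent network engine on numpy.

Implements exactly the layers the classifier architectures need — word
embedding, LSTM, 1-D and 2-D convolution, max pooling, dense, dropout — with
hand-written backward passes, Adam updates, a binary cross-entropy loss on
logits, and training-loss early stopping that restores the best checkpoint.
Everything is deterministic for a fixed seed.

Gradients are validated against central finite differences in the test
suite; keep any change to a backward pass covered there.
"""

from __future__ import annotations


import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits.ravel()
    y = y.ravel().astype(np.float64)
    # log(1 + e^z) - y z, computed stably
    loss = float(np.mean(np.logaddexp(0.0, z) - y * z))
    grad = (sigmoid(z) - y) / z.size
    return loss, grad.reshape(logits.shape)


class Layer:
    """Base layer: parameter-carrying layers fill ``params``/``grads``."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Embedding(Layer):
    """Integer tokens (n, L) -> learned vectors (n, L, dim)."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.W = rng.normal(0.0, 0.1, size=(vocab_size, dim))
        self.params = [self.W]
        self.grads = [np.zeros_like(self.W)]

    def forward(self, x, train=False):
        self._x = x
        return self.W[x]

    def backward(self, dout):
        dW = self.grads[0]
        dW[...] = 0.0
        np.add.at(dW, self._x, dout)
        return None  # integer input has no gradient


class LSTM(Layer):
    """Single-direction LSTM returning the final hidden state (n, units)."""

    def __init__(self, in_dim: int, units: int, rng: np.random.Generator):
        super().__init__()
        u = self.units = units
        scale_x = 1.0 / np.sqrt(in_dim)
        scale_h = 1.0 / np.sqrt(u)
        self.Wx = rng.uniform(-scale_x, scale_x, size=(in_dim, 4 * u))
        self.Wh = rng.uniform(-scale_h, scale_h, size=(u, 4 * u))
        self.b = np.zeros(4 * u)
        self.b[u : 2 * u] = 1.0  # forget-gate bias: remember by default
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, x, train=False):
        n, T, _ = x.shape
        u = self.units
        h = np.zeros((n, u))
        c = np.zeros((n, u))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t] @ self.Wx + h @ self.Wh + self.b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            h_prev_cache = h
            h = o * np.tanh(c)
            self._cache.append((i, f, g, o, c, c_prev, h_prev_cache))
        return h

    def backward(self, dout):
        x = self._x
        n, T, in_dim = x.shape
        u = self.units
        dWx, dWh, db = self.grads
        dWx[...] = 0.0
        dWh[...] = 0.0
        db[...] = 0.0
        dx = np.zeros_like(x)
        dh = dout
        dc = np.zeros((n, u))
        for t in range(T - 1, -1, -1):
            i, f, g, o, c, c_prev, h_prev = self._cache[t]
            tc = np.tanh(c)
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return dx


class Conv1D(Layer):
    """Valid (unpadded) 1-D convolution over (n, T, d) with ReLU option."""

    def __init__(self, in_dim: int, filters: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(kernel * in_dim)
        self.W = rng.uniform(-scale, scale, size=(kernel, in_dim, filters))
        self.b = np.zeros(filters)
        self.kernel = kernel
        self.relu = relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        # win: (n, T-k+1, d, k)
        out = np.einsum("ntdk,kdf->ntf", win, self.W) + self.b
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        x = self._x
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        dW, db = self.grads
        dW[...] = np.einsum("ntdk,ntf->kdf", win, dout)
        db[...] = dout.sum(axis=(0, 1))
        dx = np.zeros_like(x)
        T_out = dout.shape[1]
        for k in range(self.kernel):
            dx[:, k : k + T_out] += dout @ self.W[k].T
        return dx


class GlobalMaxPool1D(Layer):
    """(n, T, f) -> (n, f), max over time."""

    def forward(self, x, train=False):
        self._x_shape = x.shape
        self._argmax = x.argmax(axis=1)
        return x.max(axis=1)

    def backward(self, dout):
        n, T, f = self._x_shape
        dx = np.zeros(self._x_shape)
        ni, fi = np.meshgrid(np.arange(n), np.arange(f), indexing="ij")
        dx[ni, self._argmax, fi] = dout
        return dx


class Conv2D(Layer):
    """Valid 2-D convolution over (n, H, W, c), stride 1, ReLU option."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True):
        super().__init__()
        scale = 1.0 / np.sqrt(kernel * kernel * in_channels)
        self.W = rng.uniform(-scale, scale, size=(kernel, kernel, in_channels, filters))
        self.b = np.zeros(filters)
        self.kernel = kernel
        self.relu = relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        # win: (n, H-k+1, W-k+1, c, k, k)
        out = np.einsum("nhwcij,ijcf->nhwf", win, self.W) + self.b
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        x = self._x
        k = self.kernel
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        dW, db = self.grads
        dW[...] = np.einsum("nhwcij,nhwf->ijcf", win, dout)
        db[...] = dout.sum(axis=(0, 1, 2))
        dx = np.zeros_like(x)
        H_out, W_out = dout.shape[1], dout.shape[2]
        for i in range(k):
            for j in range(k):
                dx[:, i : i + H_out, j : j + W_out, :] += np.einsum(
                    "nhwf,cf->nhwc", dout, self.W[i, j]
                )
        return dx


class MaxPool2D(Layer):
    """Non-overlapping pool of size p over (n, H, W, f); ties share gradient."""

    def __init__(self, p: int = 2):
        super().__init__()
        self.p = p

    def forward(self, x, train=False):
        p = self.p
        n, H, W, f = x.shape
        if H % p or W % p:
            raise ValueError(f"pooling size {p} does not divide input {H}x{W}")
        r = x.reshape(n, H // p, p, W // p, p, f)
        m = r.max(axis=(2, 4), keepdims=True)
        mask = (r == m).astype(np.float64)
        self._mask = mask / mask.sum(axis=(2, 4), keepdims=True)
        self._x_shape = x.shape
        return m.reshape(n, H // p, W // p, f)

    def backward(self, dout):
        p = self.p
        n, H, W, f = self._x_shape
        d = dout.reshape(n, H // p, 1, W // p, 1, f)
        return (d * self._mask).reshape(self._x_shape)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 relu: bool = False):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim) if relu else np.sqrt(1.0 / in_dim)
        self.W = rng.normal(0.0, scale, size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.relu = relu
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=False):
        self._x = x
        out = x @ self.W + self.b
        if self.relu:
            self._mask = out > 0
            out = out * self._mask
        return out

    def backward(self, dout):
        if self.relu:
            dout = dout * self._mask
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Network:
    """A sequential stack ending in a 1-unit linear layer (the logit)."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, upto: int | None = None) -> np.ndarray:
        for layer in self.layers[:upto]:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout) -> None:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p[...] = w

    def predict_proba(self, x, batch_size: int = 1024) -> np.ndarray:
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(x[start : start + batch_size], train=False)
            out.append(sigmoid(logits.ravel()))
        return np.concatenate(out) if out else np.empty(0)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = self.beta1 * m + (1.0 - self.beta1) * g
            v[...] = self.beta2 * v + (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def fit(
    net: Network,
    X: np.ndarray,
    y: np.ndarray,
    *,
    batch_size: int = 512,
    max_epochs: int = 500,
    patience: int = 50,
    learning_rate: float = 1e-3,
    seed: int = 0,
    min_delta: float = 0.0,
) -> dict:
    """Adam + binary cross-entropy with training-loss early stopping.

    Training stops when the mean epoch training loss has not improved for
    ``patience`` consecutive epochs, and the weights of the best epoch are
    restored (smallest training loss wins).
    """
    rng = np.random.default_rng(seed)
    opt = Adam(net.parameters(), lr=learning_rate)
    n = len(X)
    history: list[float] = []
    best_loss = np.inf
    best_weights = net.get_weights()
    best_epoch = -1
    stall = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            sel = order[start : start + batch_size]
            logits = net.forward(X[sel], train=True)
            loss, dlogits = bce_with_logits(logits, y[sel])
            net.backward(dlogits)
            opt.step(net.gradients())
            losses.append(loss * len(sel))
        epoch_loss = float(np.sum(losses) / n)
        history.append(epoch_loss)
        if epoch_loss < best_loss - min_delta:
            best_loss = epoch_loss
            best_weights = net.get_weights()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break
    net.set_weights(best_weights)
    return {
        "loss": history,
        "best_epoch": best_epoch,
        "best_loss": best_loss,
        "n_epochs": len(history),
    }
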