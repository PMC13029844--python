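"""A small NumPy training engine for 1-D time-series classifiers.

Implements exactly the layer vocabulary the five architecture templates
need — 1-D convolution (plain, depthwise, pointwise), batch normalisation,
ReLU/GELU, max/global-average pooling, dropout, dense layers, residual
composition and an LSTM — together with Adam and categorical cross-entropy.
Everything runs on float64 CPU arrays; convolutions are evaluated as
im2col matrix products.

Inputs are ``(batch, channels, length)`` arrays.  All layers expose
``forward(x, training)`` / ``backward(grad)`` and publish their parameter
and gradient arrays, so the optimizer is architecture-agnostic.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "Layer",
    "Sequential",
    "Conv1D",
    "DepthwiseConv1D",
    "BatchNorm1D",
    "ReLU",
    "GELU",
    "MaxPool1D",
    "GlobalAvgPool1D",
    "Dense",
    "Dropout",
    "Residual",
    "Concat",
    "LSTM",
    "Adam",
    "softmax",
    "cross_entropy",
    "NetworkClassifier",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return float(loss), grad / n


class Layer:
    """Base layer; parameter-free unless a subclass registers arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def sublayers(self) -> list["Layer"]:
        return []

    def all_params(self) -> list[np.ndarray]:
        out = list(self.params)
        for sub in self.sublayers():
            out.extend(sub.all_params())
        return out

    def all_grads(self) -> list[np.ndarray]:
        out = list(self.grads)
        for sub in self.sublayers():
            out.extend(sub.all_grads())
        return out


class Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def sublayers(self) -> list[Layer]:
        return self.layers

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, L, C*k) sliding windows after same-padding."""
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # (B,C,L,k)
    b, c, l, _ = win.shape
    return win.transpose(0, 2, 1, 3).reshape(b, l, c * k)


def _col2im(gcols: np.ndarray, b: int, c: int, l: int, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`."""
    pad = (k - 1) // 2
    g = gcols.reshape(b, l, c, k)
    gxp = np.zeros((b, c, l + 2 * pad))
    for t in range(k):
        gxp[:, :, t : t + l] += g[:, :, :, t].transpose(0, 2, 1)
    return gxp[:, :, pad : pad + l] if pad else gxp


class Conv1D(Layer):
    """Same-padded stride-1 1-D convolution (odd kernel sizes)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * kernel))
        self.b = np.zeros(c_out)
        self.kernel = kernel
        self.c_in = c_in
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._shape = x.shape
        self._cols = _im2col(x, self.kernel)  # (B, L, C*k)
        y = self._cols @ self.w.T + self.b  # (B, L, F)
        return y.transpose(0, 2, 1)

    def backward(self, grad):
        g = grad.transpose(0, 2, 1)  # (B, L, F)
        b, c, l = self._shape
        flat_g = g.reshape(-1, g.shape[-1])
        flat_cols = self._cols.reshape(-1, self._cols.shape[-1])
        self.grads[0][...] = flat_g.T @ flat_cols
        self.grads[1][...] = flat_g.sum(axis=0)
        gcols = g @ self.w  # (B, L, C*k)
        return _col2im(gcols, b, c, l, self.kernel)


class DepthwiseConv1D(Layer):
    """Per-channel same-padded convolution (the ConvMixer spatial mixer)."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd")
        self.w = rng.normal(0.0, np.sqrt(2.0 / kernel), size=(channels, kernel))
        self.b = np.zeros(channels)
        self.kernel = kernel
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        pad = (self.kernel - 1) // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        self._win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        self._shape = x.shape
        return np.einsum("bclk,ck->bcl", self._win, self.w) + self.b[:, None]

    def backward(self, grad):
        b, c, l = self._shape
        self.grads[0][...] = np.einsum("bcl,bclk->ck", grad, self._win)
        self.grads[1][...] = grad.sum(axis=(0, 2))
        gcols = np.einsum("bcl,ck->bclk", grad, self.w)
        pad = (self.kernel - 1) // 2
        gxp = np.zeros((b, c, l + 2 * pad))
        for t in range(self.kernel):
            gxp[:, :, t : t + l] += gcols[:, :, :, t]
        return gxp[:, :, pad : pad + l] if pad else gxp


class BatchNorm1D(Layer):
    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, training=False):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) * self._invstd[:, None]
        return self.gamma[:, None] * self._xhat + self.beta[:, None]

    def backward(self, grad):
        n = grad.shape[0] * grad.shape[2]
        self.grads[0][...] = np.sum(grad * self._xhat, axis=(0, 2))
        self.grads[1][...] = grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma[:, None]
        return (
            self._invstd[:, None]
            / n
            * (
                n * gxhat
                - gxhat.sum(axis=(0, 2), keepdims=True).transpose(0, 1, 2)
                - self._xhat * np.sum(gxhat * self._xhat, axis=(0, 2))[:, None]
            )
        )


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class GELU(Layer):
    def forward(self, x, training=False):
        self._x = x
        self._cdf = 0.5 * (1.0 + special.erf(x / np.sqrt(2.0)))
        return x * self._cdf

    def backward(self, grad):
        pdf = np.exp(-0.5 * self._x**2) / np.sqrt(2.0 * np.pi)
        return grad * (self._cdf + self._x * pdf)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; degenerates to identity once L < pool."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        b, c, l = x.shape
        if l < self.pool:
            self._passthrough = True
            return x
        self._passthrough = False
        self._shape = x.shape
        l_out = l // self.pool
        xt = x[:, :, : l_out * self.pool].reshape(b, c, l_out, self.pool)
        self._arg = xt.argmax(axis=3)
        return xt.max(axis=3)

    def backward(self, grad):
        if self._passthrough:
            return grad
        b, c, l = self._shape
        l_out = grad.shape[2]
        gx = np.zeros((b, c, l_out, self.pool))
        bi, ci, li = np.ogrid[:b, :c, :l_out]
        gx[bi, ci, li, self._arg] = grad
        out = np.zeros((b, c, l))
        out[:, :, : l_out * self.pool] = gx.reshape(b, c, l_out * self.pool)
        return out


class GlobalAvgPool1D(Layer):
    def forward(self, x, training=False):
        self._l = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._l, axis=2) / self._l


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad):
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.w.T


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Residual(Layer):
    """`activation(main(x) + shortcut(x))`; identity shortcut by default."""

    def __init__(self, main: Sequential, shortcut: Layer | None = None,
                 activation: Layer | None = None):
        super().__init__()
        self.main = main
        self.shortcut = shortcut
        self.activation = activation

    def sublayers(self):
        subs = [self.main]
        if self.shortcut is not None:
            subs.append(self.shortcut)
        return subs

    def forward(self, x, training=False):
        y = self.main.forward(x, training)
        s = x if self.shortcut is None else self.shortcut.forward(x, training)
        z = y + s
        return self.activation.forward(z, training) if self.activation else z

    def backward(self, grad):
        if self.activation:
            grad = self.activation.backward(grad)
        gx = self.main.backward(grad)
        gx = gx + (grad if self.shortcut is None else self.shortcut.backward(grad))
        return gx


class Concat(Layer):
    """Parallel branches concatenated along the channel axis."""

    def __init__(self, branches: list[Layer]):
        super().__init__()
        self.branches = branches

    def sublayers(self):
        return self.branches

    def forward(self, x, training=False):
        outs = [b.forward(x, training) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1]
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        pieces = np.split(grad, self._splits, axis=1)
        return sum(b.backward(g) for b, g in zip(self.branches, pieces))


class _LSTMCell:
    """One direction of one LSTM layer (gates ordered i, f, g, o)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(hidden)
        self.wx = rng.uniform(-s, s, size=(d_in, 4 * hidden))
        self.wh = rng.uniform(-s, s, size=(hidden, 4 * hidden))
        self.b = np.zeros(4 * hidden)
        self.hidden = hidden
        self.params = [self.wx, self.wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def forward(self, xs: np.ndarray) -> np.ndarray:
        """xs: (L, B, D) -> hidden sequence (L, B, H)."""
        l, b, _ = xs.shape
        h = np.zeros((b, self.hidden))
        c = np.zeros((b, self.hidden))
        self._cache = []
        hs = np.empty((l, b, self.hidden))
        for t in range(l):
            z = xs[t] @ self.wx + h @ self.wh + self.b
            i, f, g, o = np.split(z, 4, axis=1)
            i = 1.0 / (1.0 + np.exp(-i))
            f = 1.0 / (1.0 + np.exp(-f))
            o = 1.0 / (1.0 + np.exp(-o))
            g = np.tanh(g)
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((xs[t], h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            hs[t] = h
        return hs

    def backward(self, ghs: np.ndarray) -> np.ndarray:
        """ghs: (L, B, H) gradients on the hidden sequence -> (L, B, D)."""
        l, b, _ = ghs.shape
        for g_ in self.grads:
            g_[...] = 0.0
        gxs = np.empty((l, b, self.wx.shape[0]))
        gh_next = np.zeros((b, self.hidden))
        gc_next = np.zeros((b, self.hidden))
        for t in range(l - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            gh = ghs[t] + gh_next
            go = gh * tc
            gc = gh * o * (1.0 - tc**2) + gc_next
            gi = gc * g
            gg = gc * i
            gf = gc * c_prev
            gz = np.concatenate(
                [
                    gi * i * (1.0 - i),
                    gf * f * (1.0 - f),
                    gg * (1.0 - g**2),
                    go * o * (1.0 - o),
                ],
                axis=1,
            )
            self.grads[0] += x_t.T @ gz
            self.grads[1] += h_prev.T @ gz
            self.grads[2] += gz.sum(axis=0)
            gxs[t] = gz @ self.wx.T
            gh_next = gz @ self.wh.T
            gc_next = gc * f
        return gxs


class LSTM(Layer):
    """(B, C, L) -> last hidden state (B, H * directions) or the full hidden
    sequence (B, H * directions, L) when ``return_sequence`` is set.

    Stacked layers feed the full (possibly bidirectional) hidden sequence of
    one layer into the next, mirroring the usual deep-LSTM convention.
    """

    def __init__(
        self,
        d_in: int,
        hidden: int,
        rng: np.random.Generator,
        num_layers: int = 1,
        bidirectional: bool = False,
        return_sequence: bool = False,
    ):
        super().__init__()
        self.bidirectional = bidirectional
        self.return_sequence = return_sequence
        self.cells: list[list[_LSTMCell]] = []
        d = d_in
        for _ in range(num_layers):
            layer_cells = [_LSTMCell(d, hidden, rng)]
            if bidirectional:
                layer_cells.append(_LSTMCell(d, hidden, rng))
            self.cells.append(layer_cells)
            d = hidden * (2 if bidirectional else 1)
        self.params = [p for layer in self.cells for cell in layer for p in cell.params]
        self.grads = [g for layer in self.cells for cell in layer for g in cell.grads]

    def forward(self, x, training=False):
        xs = x.transpose(2, 0, 1)  # (L, B, C)
        for layer_cells in self.cells:
            fwd = layer_cells[0].forward(xs)
            if self.bidirectional:
                bwd = layer_cells[1].forward(xs[::-1])[::-1]
                xs = np.concatenate([fwd, bwd], axis=2)
            else:
                xs = fwd
        self._out_len = xs.shape[0]
        if self.return_sequence:
            return xs.transpose(1, 2, 0)
        if self.bidirectional:
            h = xs.shape[2] // 2
            return np.concatenate([xs[-1, :, :h], xs[0, :, h:]], axis=1)
        return xs[-1]

    def backward(self, grad):
        l = self._out_len
        if self.return_sequence:
            gxs = grad.transpose(2, 0, 1)
        else:
            b = grad.shape[0]
            width = grad.shape[1]
            gxs = np.zeros((l, b, width))
            if self.bidirectional:
                h = width // 2
                gxs[-1, :, :h] = grad[:, :h]
                gxs[0, :, h:] = grad[:, h:]
            else:
                gxs[-1] = grad
        for layer_cells in reversed(self.cells):
            if self.bidirectional:
                h = gxs.shape[2] // 2
                g_f = layer_cells[0].backward(np.ascontiguousarray(gxs[:, :, :h]))
                g_b = layer_cells[1].backward(np.ascontiguousarray(gxs[::-1, :, h:]))[::-1]
                gxs = g_f + g_b
            else:
                gxs = layer_cells[0].backward(gxs)
        return gxs.transpose(1, 2, 0)


class Adam:
    """Adam with bias correction, acting on a model's flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class NetworkClassifier:
    """Trains a layer graph with Adam + categorical cross-entropy.

    Training is deterministic for a fixed seed: the seed controls weight
    initialisation (done by the architecture builder), minibatch shuffling
    and dropout masks.  Early stopping monitors validation loss and restores
    the best weights.
    """

    def __init__(self, net: Layer, rng: np.random.Generator):
        self.net = net
        self.rng = rng
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 100,
        batch_size: int = 32,
        lr: float = 1e-3,
        patience: int = 10,
    ) -> "NetworkClassifier":
        params = self.net.all_params()
        opt = Adam(params, lr=lr)
        best_loss = np.inf
        best_params = None
        strikes = 0
        n = x.shape[0]
        for _ in range(epochs):
            order = self.rng.permutation(n)
            total = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                logits = self.net.forward(x[idx], training=True)
                loss, grad = cross_entropy(logits, y[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                self.net.backward(grad)
                opt.step(self.net.all_grads())
                total += loss * idx.size
            self.history["train_loss"].append(total / n)
            if x_val is not None and x_val.shape[0] > 0:
                val_loss, _ = cross_entropy(self._logits(x_val), y_val)
                self.history["val_loss"].append(val_loss)
                if val_loss < best_loss - 1e-6:
                    best_loss = val_loss
                    best_params = [p.copy() for p in params]
                    strikes = 0
                else:
                    strikes += 1
                    if strikes >= patience:
                        break
        if best_params is not None:
            for p, bp in zip(params, best_params):
                p[...] = bp
        return self

    def _logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        outs = [
            self.net.forward(x[s : s + batch_size], training=False)
            for s in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if x.shape[0] == 0:
            return np.zeros((0, 1))
        return softmax(self._logits(x))
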