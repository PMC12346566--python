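"""Minimal sequence-model toolkit (numpy, manual backprop).

Implements exactly the layers the lung-sound diagnoser needs: 1-D
convolution, batch normalization, max pooling, LSTM, temporal attention
pooling, dropout and dense layers, with categorical cross-entropy and an
Adam optimizer. Forward passes follow the textbook recurrences (sigmoid
gates, tanh candidate, softmax attention over time steps); every
backward pass is verified in the test suite against finite differences.

Shapes are batch-first: sequence tensors are (B, T, F), vectors (B, D).
All math is float64 so gradient checks are meaningful.
"""

from __future__ import annotations

import copy

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def softmax(x, axis=-1):
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def orthogonal(rng, rows, cols):
    """Orthogonal matrix init (QR of a Gaussian), standard for recurrent
    kernels: preserves norms across many time steps."""
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


class Layer:
    """Base class: parameter dict, gradient dict, forward/backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        #: parameter names subject to L2 weight decay (kernels only)
        self.decayed: tuple[str, ...] = ()

    def forward(self, x, training=False):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv1D(Layer):
    """Temporal convolution, window anchored at t: y_t = act(sum_k w_k x_{t+k} + b).

    The input is zero-padded on the right by kernel-1 so the output keeps
    the input length ("same" framing of the window-at-t convention).
    """

    def __init__(self, in_ch, out_ch, kernel, rng, activation="relu"):
        super().__init__()
        self.kernel = kernel
        self.activation = activation
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.params = {
            "W": rng.normal(0.0, scale, size=(kernel * in_ch, out_ch)),
            "b": np.zeros(out_ch),
        }
        self.decayed = ("W",)

    def forward(self, x, training=False):
        B, T, C = x.shape
        xpad = np.pad(x, ((0, 0), (0, self.kernel - 1), (0, 0)))
        patches = sliding_window_view(xpad, self.kernel, axis=1)  # (B,T,C,k)
        patches = patches.transpose(0, 1, 3, 2).reshape(B, T, self.kernel * C)
        z = patches @ self.params["W"] + self.params["b"]
        self._cache = (patches, z, (B, T, C))
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dout):
        patches, z, (B, T, C) = self._cache
        dz = dout * (z > 0) if self.activation == "relu" else dout
        self.grads["W"] = patches.reshape(-1, patches.shape[-1]).T @ dz.reshape(-1, dz.shape[-1])
        self.grads["b"] = dz.sum(axis=(0, 1))
        dpatch = dz @ self.params["W"].T  # (B,T,k*C)
        dpatch = dpatch.reshape(B, T, self.kernel, C)
        dxpad = np.zeros((B, T + self.kernel - 1, C))
        for k in range(self.kernel):
            dxpad[:, k:k + T, :] += dpatch[:, :, k, :]
        return dxpad[:, :T, :]


class BatchNorm1D(Layer):
    """Per-channel normalization over batch and time, with running stats."""

    def __init__(self, channels, momentum=0.99, eps=1e-3):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(channels), "beta": np.zeros(channels)}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv, x.shape[0] * x.shape[1])
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout):
        xhat, inv, N = self._cache
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 1))
        self.grads["beta"] = dout.sum(axis=(0, 1))
        dxhat = dout * self.params["gamma"]
        return inv * (dxhat - dxhat.mean(axis=(0, 1))
                      - xhat * (dxhat * xhat).mean(axis=(0, 1)))


class MaxPool1D(Layer):
    def __init__(self, pool=2):
        super().__init__()
        self.pool = pool

    def forward(self, x, training=False):
        B, T, C = x.shape
        Tp = T // self.pool
        xr = x[:, : Tp * self.pool, :].reshape(B, Tp, self.pool, C)
        self._argmax = xr.argmax(axis=2)
        self._shape = (B, T, C)
        return xr.max(axis=2)

    def backward(self, dout):
        B, T, C = self._shape
        Tp = dout.shape[1]
        dx = np.zeros((B, Tp, self.pool, C))
        b, t, c = np.meshgrid(np.arange(B), np.arange(Tp), np.arange(C),
                              indexing="ij")
        dx[b, t, self._argmax, c] = dout
        out = np.zeros((B, T, C))
        out[:, : Tp * self.pool, :] = dx.reshape(B, Tp * self.pool, C)
        return out


def lstm_cell_step(x_t, h_prev, c_prev, weights):
    """One LSTM step: sigmoid forget/input/output gates, tanh candidate.

    ``weights`` maps Wx (F,4H), Wh (H,4H), b (4H,), gate order f,i,g,o.
    Returns (h_t, c_t).
    """
    Wx, Wh, b = weights["Wx"], weights["Wh"], weights["b"]
    H = Wh.shape[0]
    if x_t.shape[-1] != Wx.shape[0] or h_prev.shape[-1] != H:
        raise ValueError("dimension mismatch in lstm_cell_step")
    z = x_t @ Wx + h_prev @ Wh + b
    f = sigmoid(z[..., :H])
    i = sigmoid(z[..., H:2 * H])
    g = np.tanh(z[..., 2 * H:3 * H])
    o = sigmoid(z[..., 3 * H:])
    c_t = f * c_prev + i * g
    h_t = o * np.tanh(c_t)
    return h_t, c_t


class LSTM(Layer):
    def __init__(self, in_dim, units, rng, return_sequences=True):
        super().__init__()
        self.units = units
        self.return_sequences = return_sequences
        s_in = np.sqrt(2.0 / (in_dim + 4 * units))
        self.params = {
            "Wx": rng.normal(0.0, s_in, size=(in_dim, 4 * units)),
            "Wh": np.concatenate(
                [orthogonal(rng, units, units) for _ in range(4)], axis=1),
            "b": np.zeros(4 * units),
        }
        # positive forget-gate bias: standard stabilization
        self.params["b"][:units] = 1.0
        self.decayed = ("Wx", "Wh")

    def forward(self, x, training=False):
        B, T, F = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        cache = []
        hs = np.zeros((B, T, H))
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        for t in range(T):
            z = x[:, t, :] @ Wx + h @ Wh + b
            f = sigmoid(z[:, :H])
            i = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, t, :], h, c, f, i, g, o, tanh_c))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache = cache
        self._x_shape = x.shape
        return hs if self.return_sequences else h

    def backward(self, dout):
        B, T, F = self._x_shape
        H = self.units
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.zeros((B, T, F))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, f, i, g, o, tanh_c = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dout[:, t, :]
            elif t == T - 1:
                dh += dout
            do = dh * tanh_c
            dc = dc_next + dh * o * (1.0 - tanh_c**2)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                df * f * (1 - f),
                di * i * (1 - i),
                dg * (1 - g**2),
                do * o * (1 - o),
            ], axis=1)
            dWx += x_t.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh_next = dz @ Wh.T
        self.grads = {"Wx": dWx, "Wh": dWh, "b": db}
        return dx


class AttentionPool(Layer):
    """Temporal attention: two-stage scoring then softmax over time.

    Scores: u_t = tanh(h_t W1 + b1) (hidden units), e_t = u_t w2 + b2 (one
    score per step), alpha = softmax over steps. The output is the
    attention-weighted sequence {T * alpha_t * h_t}, scaled by the step
    count so its magnitude is independent of sequence length (uniform
    attention reproduces the input sequence exactly); its time average is
    the context vector sum_t alpha_t h_t. ``mode='uniform'`` replaces
    attention by uniform weights alpha_t = 1/T (mean pooling in the
    context-vector reading).
    """

    def __init__(self, in_dim, hidden, rng, mode="attention"):
        super().__init__()
        self.mode = mode
        self.last_alpha: np.ndarray | None = None
        if mode == "attention":
            s = np.sqrt(1.0 / in_dim)
            self.params = {
                "W1": rng.normal(0.0, s, size=(in_dim, hidden)),
                "b1": np.zeros(hidden),
                "w2": rng.normal(0.0, np.sqrt(1.0 / hidden), size=(hidden, 1)),
                "b2": np.zeros(1),
            }
            self.decayed = ("W1", "w2")

    def scores(self, h):
        u = np.tanh(h @ self.params["W1"] + self.params["b1"])
        e = u @ self.params["w2"] + self.params["b2"]
        return u, e[..., 0]

    def forward(self, h, training=False):
        B, T, H = h.shape
        if self.mode == "uniform":
            alpha = np.full((B, T), 1.0 / T)
            self._cache = (h, None, alpha)
        else:
            u, e = self.scores(h)
            alpha = softmax(e, axis=1)
            self._cache = (h, u, alpha)
        self.last_alpha = alpha
        return (h.shape[1] * alpha)[:, :, None] * h

    def backward(self, dout):
        h, u, alpha = self._cache
        T = h.shape[1]
        dout = T * dout
        dh = alpha[:, :, None] * dout
        if self.mode == "uniform":
            return dh
        dalpha = (dout * h).sum(axis=2)  # (B,T)
        de = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
        du = de[:, :, None] * self.params["w2"][None, None, :, 0]
        du_pre = du * (1.0 - u**2)
        B, T, H = h.shape
        self.grads = {
            "w2": (u * de[:, :, None]).reshape(-1, u.shape[-1]).sum(axis=0)[:, None],
            "b2": np.array([de.sum()]),
            "W1": h.reshape(-1, H).T @ du_pre.reshape(-1, du_pre.shape[-1]),
            "b1": du_pre.sum(axis=(0, 1)),
        }
        dh += du_pre @ self.params["W1"].T
        return dh


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._T, axis=1) / self._T


class Dropout(Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Dense(Layer):
    def __init__(self, in_dim, out_dim, rng, activation=None):
        super().__init__()
        self.activation = activation
        scale = np.sqrt(2.0 / in_dim) if activation == "relu" else np.sqrt(1.0 / in_dim)
        self.params = {
            "W": rng.normal(0.0, scale, size=(in_dim, out_dim)),
            "b": np.zeros(out_dim),
        }
        self.decayed = ("W",)

    def forward(self, x, training=False):
        z = x @ self.params["W"] + self.params["b"]
        self._cache = (x, z)
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dout):
        x, z = self._cache
        dz = dout * (z > 0) if self.activation == "relu" else dout
        self.grads["W"] = x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x):
        return softmax(self.forward(x, training=False), axis=-1)

    def activations(self, x):
        """Per-layer outputs of an inference-mode forward pass."""
        outs = []
        for layer in self.layers:
            x = layer.forward(x, training=False)
            outs.append(x)
        return outs

    def parameters(self):
        for layer in self.layers:
            for name, value in layer.params.items():
                yield layer, name, value

    def get_weights(self):
        state = [copy.deepcopy(layer.params) for layer in self.layers]
        extra = [(copy.deepcopy(layer.running_mean), copy.deepcopy(layer.running_var))
                 if isinstance(layer, BatchNorm1D) else None
                 for layer in self.layers]
        return state, extra

    def set_weights(self, weights):
        state, extra = weights
        for layer, params, ex in zip(self.layers, state, extra):
            layer.params = copy.deepcopy(params)
            if ex is not None:
                layer.running_mean, layer.running_var = copy.deepcopy(ex)


def softmax_cross_entropy(logits, y_onehot):
    """Mean categorical cross-entropy; returns (loss, dlogits)."""
    p = softmax(logits, axis=-1)
    B = logits.shape[0]
    loss = -np.sum(y_onehot * np.log(np.maximum(p, 1e-12))) / B
    return loss, (p - y_onehot) / B


class Adam:
    def __init__(self, model, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7,
                 l2=0.0, clipnorm=None):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.clipnorm = clipnorm
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self):
        self.t += 1
        clip = 1.0
        if self.clipnorm is not None:
            total = 0.0
            for layer in self.model.layers:
                for g in layer.grads.values():
                    total += float(np.sum(g * g))
            norm = np.sqrt(total)
            if norm > self.clipnorm:
                clip = self.clipnorm / norm
        for li, layer in enumerate(self.model.layers):
            for name in layer.params:
                g = layer.grads.get(name)
                if g is None:
                    continue
                g = g * clip
                if self.l2 and name in layer.decayed:
                    g = g + 2.0 * self.l2 * layer.params[name]
                key = (li, name)
                m = self.m.get(key, np.zeros_like(g))
                v = self.v.get(key, np.zeros_like(g))
                m = self.beta1 * m + (1 - self.beta1) * g
                v = self.beta2 * v + (1 - self.beta2) * g**2
                self.m[key], self.v[key] = m, v
                mhat = m / (1 - self.beta1**self.t)
                vhat = v / (1 - self.beta2**self.t)
                layer.params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopping:
    """Stop after ``patience`` epochs without validation-loss improvement;
    remembers the best epoch's weights for restoration."""

    def __init__(self, patience=10):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.best_weights = None
        self.wait = 0

    def update(self, epoch, val_loss, weights=None) -> bool:
        """Record epoch (1-based); returns True when training should stop."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.best_weights = weights
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience
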