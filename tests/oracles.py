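"""Independent brute-force transcriptions used as oracles.

Each function re-implements a forward pass with explicit loops, straight
from the layer's mathematical definition, sharing no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def conv1d_bruteforce(x, W, b, kernel):
    """y[b,t,o] = relu(sum_k sum_c W[k*C+c, o] * xpad[b, t+k, c] + b[o])."""
    B, T, C = x.shape
    out_ch = W.shape[1]
    xpad = np.zeros((B, T + kernel - 1, C))
    xpad[:, :T, :] = x
    y = np.zeros((B, T, out_ch))
    for bi in range(B):
        for t in range(T):
            for o in range(out_ch):
                acc = b[o]
                for k in range(kernel):
                    for c in range(C):
                        acc += W[k * C + c, o] * xpad[bi, t + k, c]
                y[bi, t, o] = max(acc, 0.0)
    return y


def batchnorm_bruteforce(x, gamma, beta, eps):
    """Per-channel (x - mu) / sqrt(var + eps), batch statistics."""
    B, T, C = x.shape
    y = np.zeros_like(x)
    for c in range(C):
        vals = x[:, :, c].ravel()
        mu = vals.mean()
        var = vals.var()
        y[:, :, c] = gamma[c] * (x[:, :, c] - mu) / np.sqrt(var + eps) + beta[c]
    return y


def maxpool_bruteforce(x, pool):
    B, T, C = x.shape
    Tp = T // pool
    y = np.zeros((B, Tp, C))
    for bi in range(B):
        for t in range(Tp):
            for c in range(C):
                y[bi, t, c] = max(x[bi, t * pool + j, c] for j in range(pool))
    return y


def lstm_bruteforce(x, Wx, Wh, b):
    """Sequence of hidden states from the gate recurrences, one scalar
    op at a time: f/i/o sigmoid gates, tanh candidate, cell update."""
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    B, T, F = x.shape
    H = Wh.shape[0]
    hs = np.zeros((B, T, H))
    for bi in range(B):
        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(T):
            z = x[bi, t] @ Wx + h @ Wh + b
            f = sig(z[:H])
            i = sig(z[H:2 * H])
            g = np.tanh(z[2 * H:3 * H])
            o = sig(z[3 * H:])
            c = f * c + i * g
            h = o * np.tanh(c)
            hs[bi, t] = h
    return hs


def attention_bruteforce(h, W1, b1, w2, b2):
    """Two-stage scores, softmax over steps, weighted sequence (x T)."""
    B, T, H = h.shape
    out = np.zeros_like(h)
    alphas = np.zeros((B, T))
    for bi in range(B):
        e = np.zeros(T)
        for t in range(T):
            u = np.tanh(h[bi, t] @ W1 + b1)
            e[t] = u @ w2[:, 0] + b2[0]
        ex = np.exp(e - e.max())
        alpha = ex / ex.sum()
        alphas[bi] = alpha
        for t in range(T):
            out[bi, t] = T * alpha[t] * h[bi, t]
    return out, alphas


def kappa_from_table(a_both, a_only1, a_only2, neither):
    """Cohen's kappa for a 2x2 agreement table by the closed form."""
    n = a_both + a_only1 + a_only2 + neither
    p_o = (a_both + neither) / n
    p_yes1 = (a_both + a_only1) / n
    p_yes2 = (a_both + a_only2) / n
    p_e = p_yes1 * p_yes2 + (1 - p_yes1) * (1 - p_yes2)
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1 - p_e)


def wilson_interval(correct, total, z=1.959963984540054):
    """Wilson score interval, closed form."""
    p = correct / total
    denom = 1 + z**2 / total
    center = (p + z**2 / (2 * total)) / denom
    half = z * np.sqrt(p * (1 - p) / total + z**2 / (4 * total**2)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def numerical_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
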