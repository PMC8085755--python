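"""A small bidirectional LSTM binary classifier in pure numpy.

The sequence lengths (21 steps) and widths (32 inputs, 32 hidden units per
direction) involved here are tiny, so a vectorised numpy implementation
with explicit backpropagation through time trains in seconds on one CPU and
keeps the package dependency-light. Determinism is exact: given a seed, the
initial weights, batch order and hence final weights are reproducible
bit-for-bit.

Architecture: one LSTM layer per direction; the final hidden states of the
two directions are concatenated and passed through a dense layer with a
logistic output. Loss is binary cross-entropy; the optimiser is Adam.

Gate order inside the packed weight matrices is (input, forget, cell,
output). Forget-gate biases are initialised at 1, a standard stabiliser.
"""

from __future__ import annotations

import numpy as np


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def init_params(input_dim: int, hidden_size: int, seed: int) -> dict[str, np.ndarray]:
    """Uniform(-k, k) init with k = 1/sqrt(hidden_size), seeded."""
    rng = np.random.default_rng(seed)
    k = 1.0 / np.sqrt(hidden_size)
    h4 = 4 * hidden_size

    def u(*shape):
        return rng.uniform(-k, k, size=shape)

    params = {}
    for d in ("fw", "bw"):
        params[f"Wx_{d}"] = u(input_dim, h4)
        params[f"Wh_{d}"] = u(hidden_size, h4)
        b = u(h4)
        b[hidden_size : 2 * hidden_size] = 1.0  # forget bias
        params[f"b_{d}"] = b
    params["w_out"] = u(2 * hidden_size)
    params["b_out"] = np.zeros(1)
    return params


def _lstm_forward(X: np.ndarray, Wx: np.ndarray, Wh: np.ndarray, b: np.ndarray):
    """Run an LSTM over X (B, T, d); return final hidden state and cache."""
    B, T, _ = X.shape
    h = Wh.shape[0]
    hs = np.zeros((T + 1, B, h))
    cs = np.zeros((T + 1, B, h))
    gates = np.empty((T, B, 4 * h))
    for t in range(T):
        z = X[:, t] @ Wx + hs[t] @ Wh + b
        i = sigmoid(z[:, :h])
        f = sigmoid(z[:, h : 2 * h])
        g = np.tanh(z[:, 2 * h : 3 * h])
        o = sigmoid(z[:, 3 * h :])
        c = f * cs[t] + i * g
        hs[t + 1] = o * np.tanh(c)
        cs[t + 1] = c
        gates[t] = np.concatenate([i, f, g, o], axis=1)
    return hs, cs, gates


def _lstm_backward(X, Wh, hs, cs, gates, dh_final):
    """Gradient of a scalar loss wrt LSTM params, given d(loss)/d(final h)."""
    T = X.shape[1]
    h = Wh.shape[0]
    dWx = np.zeros((X.shape[2], 4 * h))
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * h)
    dh = dh_final
    dc = np.zeros_like(dh_final)
    for t in range(T - 1, -1, -1):
        i = gates[t][:, :h]
        f = gates[t][:, h : 2 * h]
        g = gates[t][:, 2 * h : 3 * h]
        o = gates[t][:, 3 * h :]
        tc = np.tanh(cs[t + 1])
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc * tc)
        di = dc * g
        dg = dc * i
        df = dc * cs[t]
        dc = dc * f
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g), do * o * (1 - o)],
            axis=1,
        )
        dWx += X[:, t].T @ dz
        dWh += hs[t].T @ dz
        db += dz.sum(axis=0)
        dh = dz @ Wh.T
    return dWx, dWh, db


def forward(params: dict[str, np.ndarray], X: np.ndarray) -> np.ndarray:
    """Class probabilities for X (B, T, d); pure function of (params, X)."""
    hs_f, _, _ = _lstm_forward(X, params["Wx_fw"], params["Wh_fw"], params["b_fw"])
    Xr = X[:, ::-1]
    hs_b, _, _ = _lstm_forward(Xr, params["Wx_bw"], params["Wh_bw"], params["b_bw"])
    hcat = np.concatenate([hs_f[-1], hs_b[-1]], axis=1)
    return sigmoid(hcat @ params["w_out"] + params["b_out"][0])


def loss_and_grads(params, X, y):
    """Mean binary cross-entropy and gradients for a batch."""
    hs_f, cs_f, g_f = _lstm_forward(X, params["Wx_fw"], params["Wh_fw"], params["b_fw"])
    Xr = np.ascontiguousarray(X[:, ::-1])
    hs_b, cs_b, g_b = _lstm_forward(Xr, params["Wx_bw"], params["Wh_bw"], params["b_bw"])
    hcat = np.concatenate([hs_f[-1], hs_b[-1]], axis=1)
    logit = hcat @ params["w_out"] + params["b_out"][0]
    p = sigmoid(logit)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))

    B = X.shape[0]
    h = params["Wh_fw"].shape[0]
    dlogit = (p - y) / B
    grads = {
        "w_out": hcat.T @ dlogit,
        "b_out": np.array([dlogit.sum()]),
    }
    dhcat = np.outer(dlogit, params["w_out"])
    dWx, dWh, db = _lstm_backward(X, params["Wh_fw"], hs_f, cs_f, g_f, dhcat[:, :h])
    grads["Wx_fw"], grads["Wh_fw"], grads["b_fw"] = dWx, dWh, db
    dWx, dWh, db = _lstm_backward(Xr, params["Wh_bw"], hs_b, cs_b, g_b, dhcat[:, h:])
    grads["Wx_bw"], grads["Wh_bw"], grads["b_bw"] = dWx, dWh, db
    return loss, grads


class Adam:
    """Adam optimiser over a dict of parameter arrays (standard defaults)."""

    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k in params:
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * grads[k] ** 2
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_loop(params, X, y, lr, epochs, batch_size, seed):
    """Seeded minibatch training; returns the per-epoch mean loss history."""
    rng = np.random.default_rng(seed)
    opt = Adam(params, lr)
    n = X.shape[0]
    history = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss, grads = loss_and_grads(params, X[idx], y[idx])
            opt.step(params, grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
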