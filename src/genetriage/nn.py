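"""Minimal NumPy neural-network primitives.

Implements exactly what the package needs — a masked LSTM layer with full
backpropagation-through-time, softmax cross-entropy, and SGD/Adam
optimizers — in float64 for bitwise-reproducible training under a fixed
seed. Gate order throughout is (input, forget, cell, output).

The masked recurrence freezes hidden and cell states at padded positions
(``h_t = m·h_new + (1−m)·h_prev``), so the state after the last processed
step equals the state at each sequence's true final position and padding
cannot leak signal into the representation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "sigmoid",
    "init_lstm_params",
    "lstm_forward",
    "lstm_backward",
    "reverse_valid",
    "softmax",
    "softmax_xent",
    "SGD",
    "Adam",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_xent(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and gradient w.r.t. logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = -float(np.mean(np.log(probs[np.arange(n), labels] + 1e-12)))
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / n


def init_lstm_params(in_dim: int, hidden: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Scaled-normal init; forget-gate bias starts at 1 to ease gradient flow."""
    p = {
        "Wx": rng.normal(0.0, 1.0 / np.sqrt(in_dim), (in_dim, 4 * hidden)),
        "Wh": rng.normal(0.0, 1.0 / np.sqrt(hidden), (hidden, 4 * hidden)),
        "b": np.zeros(4 * hidden),
    }
    p["b"][hidden : 2 * hidden] = 1.0
    return p


def lstm_forward(
    X: np.ndarray, mask: np.ndarray, params: dict[str, np.ndarray]
) -> tuple[np.ndarray, dict]:
    """Run a masked LSTM over ``X`` (B, T, D) with ``mask`` (B, T) in {0,1}.

    Returns the hidden-state sequence (B, T, H) and a cache for
    :func:`lstm_backward`. States carry over unchanged where mask is 0.
    """
    B, T, _ = X.shape
    H = params["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    H_seq = np.empty((B, T, H))
    steps = []
    for t in range(T):
        a = X[:, t] @ params["Wx"] + h @ params["Wh"] + params["b"]
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H : 2 * H])
        g = np.tanh(a[:, 2 * H : 3 * H])
        o = sigmoid(a[:, 3 * H :])
        c_hat = f * c + i * g
        tanh_c = np.tanh(c_hat)
        h_hat = o * tanh_c
        m = mask[:, t : t + 1]
        steps.append((h, c, i, f, g, o, c_hat, tanh_c, m))
        c = m * c_hat + (1.0 - m) * c
        h = m * h_hat + (1.0 - m) * h
        H_seq[:, t] = h
    cache = {"X": X, "steps": steps, "H": H, "params": params}
    return H_seq, cache


def lstm_backward(dH_seq: np.ndarray, cache: dict) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backprop through :func:`lstm_forward`.

    ``dH_seq`` holds gradients w.r.t. every output position (add any
    final-state gradient at the last time index — masking routes it to each
    sequence's true final state). Returns (dX, parameter gradients).
    """
    X, steps, H, params = cache["X"], cache["steps"], cache["H"], cache["params"]
    B, T, _ = X.shape
    dX = np.zeros_like(X)
    grads = {k: np.zeros_like(v) for k, v in params.items()}
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, c_hat, tanh_c, m = steps[t]
        dh = dH_seq[:, t] + dh_next
        dh_hat = m * dh
        dc = dc_next + dh_hat * o * (1.0 - tanh_c**2)
        dc_hat = m * dc
        do = dh_hat * tanh_c
        di = dc_hat * g
        df = dc_hat * c_prev
        dg = dc_hat * i
        da = np.concatenate(
            [di * i * (1.0 - i), df * f * (1.0 - f), dg * (1.0 - g**2), do * o * (1.0 - o)],
            axis=1,
        )
        grads["Wx"] += X[:, t].T @ da
        grads["Wh"] += h_prev.T @ da
        grads["b"] += da.sum(axis=0)
        dX[:, t] = da @ params["Wx"].T
        dh_next = da @ params["Wh"].T + (1.0 - m) * dh
        dc_next = (1.0 - m) * dc + dc_hat * f
    return dX, grads


def reverse_valid(X: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its true length, leaving padding in place.

    An involution, and its own transpose — reuse it to route gradients for
    a backward-direction LSTM.
    """
    B, T = X.shape[0], X.shape[1]
    t = np.arange(T)[None, :]
    lens = lengths[:, None]
    idx = np.where(t < lens, lens - 1 - t, t)
    return X[np.arange(B)[:, None], idx]


class SGD:
    """Plain stochastic gradient descent."""

    def __init__(self, lr: float):
        self.lr = lr

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k in params:
            params[k] -= self.lr * grads[k]


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style)."""

    def __init__(
        self,
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k in params:
            if k not in self.m:
                self.m[k] = np.zeros_like(params[k])
                self.v[k] = np.zeros_like(params[k])
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * grads[k]
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * grads[k] ** 2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.weight_decay:
                params[k] -= self.lr * self.weight_decay * params[k]
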