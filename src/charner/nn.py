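"""Minimal neural primitives for the tagger: a masked batched LSTM with
hand-derived backpropagation, sequence reversal helpers, and Adam.

Everything is plain float64 numpy.  Shapes follow the (batch, time,
feature) convention; ``mask`` is (B, L) with 1.0 on real positions and
0.0 on padding.  At padded steps the LSTM carries its state through
unchanged, so padded batches and per-sequence runs produce identical
outputs at real positions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def uniform_init(rng: np.random.Generator, *shape: int, scale: float = 0.1) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


def lstm_params(rng: np.random.Generator, d_in: int, d_hidden: int) -> dict[str, np.ndarray]:
    """Gate order along the 4H axis: input, forget, cell, output.
    Forget-gate bias starts at 1.0 (standard memorization aid)."""
    p = {
        "Wx": uniform_init(rng, d_in, 4 * d_hidden),
        "Wh": uniform_init(rng, d_hidden, 4 * d_hidden),
        "b": np.zeros(4 * d_hidden),
    }
    p["b"][d_hidden : 2 * d_hidden] = 1.0
    return p


def lstm_forward(
    x: np.ndarray, mask: np.ndarray, p: dict[str, np.ndarray]
) -> tuple[np.ndarray, dict]:
    """Run an LSTM over (B, L, D) input; returns hidden states (B, L, H)
    and a cache for the backward pass."""
    B, L, _ = x.shape
    H = p["Wh"].shape[0]
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    hs = np.empty((B, L, H))
    cache: dict = {"steps": [], "x": x, "mask": mask}
    for t in range(L):
        m = mask[:, t][:, None]
        z = x[:, t] @ p["Wx"] + h @ p["Wh"] + p["b"]
        i = sigmoid(z[:, :H])
        f = sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = sigmoid(z[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        cache["steps"].append((h, c, i, f, g, o, c_new, tanh_c, m))
        c = m * c_new + (1 - m) * c
        h = m * h_new + (1 - m) * h
        hs[:, t] = h
    return hs, cache


def lstm_backward(
    d_hs: np.ndarray, p: dict[str, np.ndarray], cache: dict
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Backprop through :func:`lstm_forward`.

    ``d_hs`` is the gradient w.r.t. the full hidden-state sequence.
    Returns the gradient w.r.t. the input and a parameter-gradient dict.
    """
    x, mask = cache["x"], cache["mask"]
    B, L, D = x.shape
    H = p["Wh"].shape[0]
    grads = {"Wx": np.zeros_like(p["Wx"]), "Wh": np.zeros_like(p["Wh"]), "b": np.zeros_like(p["b"])}
    dx = np.zeros_like(x)
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in range(L - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = cache["steps"][t]
        dh_total = d_hs[:, t] + dh_next
        # Carried state at padded steps: gradient flows straight through.
        dh = m * dh_total
        dh_carry = (1 - m) * dh_total
        dc = m * dc_next
        dc_carry = (1 - m) * dc_next

        do = dh * tanh_c
        dc_new = dh * o * (1 - tanh_c**2) + dc
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        grads["Wx"] += x[:, t].T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dx[:, t] = dz @ p["Wx"].T
        dh_next = dz @ p["Wh"].T + dh_carry
        dc_next = dc_new * f + dc_carry
    return dx, grads


def reverse_padded(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Reverse each sequence within its true length, keeping padding at
    the tail.  Involutive: applying it twice restores the input."""
    out = np.array(x, copy=True)
    for b, n in enumerate(lengths):
        out[b, :n] = x[b, :n][::-1]
    return out


class Adam:
    """Adam over a flat dict of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for k, g in grads.items():
            if k not in self.params:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            self.params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
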