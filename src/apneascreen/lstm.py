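"""A minimal numpy LSTM binary classifier.

One LSTM layer with the standard cell (input/forget/output gates, tanh
cell candidate), a final-hidden-state read-out through a single sigmoid
unit, binary cross-entropy loss, and an Adam optimizer.  Sequences are
pre-padded with zeros and masked: at a masked timestep the hidden and
cell states carry over unchanged, so padding never alters the result.

Everything is seeded and runs in float32: two fits with the same seed
and data produce bit-identical parameters and predictions on one
machine.

Shapes: input ``X`` is ``(B, T, D)`` with mask ``(B, T)``; gate weights
are packed ``[i, f, g, o]`` along the last axis.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTMParams", "init_params", "forward", "loss_and_gradients", "AdamState", "adam_step"]

DTYPE = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMParams(dict):
    """Parameter container: Wx (D,4H), Wh (H,4H), b (4H,), w_out (H,), b_out (1,)."""

    @property
    def hidden_units(self) -> int:
        return self["Wh"].shape[0]

    @property
    def input_dim(self) -> int:
        return self["Wx"].shape[0]


def init_params(input_dim: int, hidden_units: int, seed: int) -> LSTMParams:
    """Glorot-uniform weights, zero biases except a +1 forget-gate bias."""
    rng = np.random.default_rng(seed)
    h = hidden_units

    def glorot(fan_in: int, fan_out: int, shape: tuple) -> np.ndarray:
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-limit, limit, size=shape).astype(DTYPE)

    b = np.zeros(4 * h, dtype=DTYPE)
    b[h : 2 * h] = 1.0  # forget gate open at init
    return LSTMParams(
        Wx=glorot(input_dim, h, (input_dim, 4 * h)),
        Wh=glorot(h, h, (h, 4 * h)),
        b=b,
        w_out=glorot(h, 1, (h,)),
        b_out=np.zeros(1, dtype=DTYPE),
    )


def forward(params: LSTMParams, X: np.ndarray, mask: np.ndarray, want_cache: bool = False):
    """Run the LSTM over a padded batch; return class-1 probabilities.

    Returns ``probs`` of shape (B,), plus the activation cache when
    ``want_cache`` (used by :func:`loss_and_gradients`).
    """
    X = np.ascontiguousarray(X, dtype=DTYPE)
    mask = np.ascontiguousarray(mask, dtype=DTYPE)
    B, T, D = X.shape
    H = params.hidden_units
    h = np.zeros((B, H), dtype=DTYPE)
    c = np.zeros((B, H), dtype=DTYPE)
    # input contribution for all timesteps in one matmul
    zin = X.reshape(B * T, D) @ params["Wx"]
    zin = (zin + params["b"]).reshape(B, T, 4 * H)

    cache = {
        "i": np.empty((T, B, H), DTYPE),
        "f": np.empty((T, B, H), DTYPE),
        "g": np.empty((T, B, H), DTYPE),
        "o": np.empty((T, B, H), DTYPE),
        "c_prev": np.empty((T, B, H), DTYPE),
        "tanh_c": np.empty((T, B, H), DTYPE),
        "h_prev": np.empty((T, B, H), DTYPE),
    } if want_cache else None

    for t in range(T):
        gates = zin[:, t, :] + h @ params["Wh"]
        i = _sigmoid(gates[:, :H])
        f = _sigmoid(gates[:, H : 2 * H])
        g = np.tanh(gates[:, 2 * H : 3 * H])
        o = _sigmoid(gates[:, 3 * H :])
        c_new = f * c + i * g
        tanh_c = np.tanh(c_new)
        h_new = o * tanh_c
        m = mask[:, t : t + 1]
        if want_cache:
            cache["i"][t] = i
            cache["f"][t] = f
            cache["g"][t] = g
            cache["o"][t] = o
            cache["c_prev"][t] = c
            cache["tanh_c"][t] = tanh_c
            cache["h_prev"][t] = h
        c = m * c_new + (1.0 - m) * c
        h = m * h_new + (1.0 - m) * h

    logits = h @ params["w_out"] + params["b_out"]
    probs = _sigmoid(logits)
    if want_cache:
        return probs, {"acts": cache, "h_final": h, "X": X, "mask": mask}
    return probs


def loss_and_gradients(params: LSTMParams, X: np.ndarray, mask: np.ndarray, y: np.ndarray):
    """Mean binary cross-entropy and its gradients via BPTT."""
    probs, full = forward(params, X, mask, want_cache=True)
    acts, h_final = full["acts"], full["h_final"]
    Xc, maskc = full["X"], full["mask"]
    B, T, D = Xc.shape
    H = params.hidden_units
    y = y.astype(DTYPE)
    eps = DTYPE(1e-7)
    p = np.clip(probs, eps, 1 - eps)
    loss = float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    dlogit = ((probs - y) / B).astype(DTYPE)  # (B,)
    grads = {
        "w_out": h_final.T @ dlogit,
        "b_out": np.array([dlogit.sum()], dtype=DTYPE),
    }
    dh = np.outer(dlogit, params["w_out"]).astype(DTYPE)  # (B, H)
    dc = np.zeros((B, H), dtype=DTYPE)
    dA = np.empty((T, B, 4 * H), dtype=DTYPE)
    dWh = np.zeros_like(params["Wh"])
    WhT = params["Wh"].T

    for t in range(T - 1, -1, -1):
        m = maskc[:, t : t + 1]
        i, f, g, o = acts["i"][t], acts["f"][t], acts["g"][t], acts["o"][t]
        tanh_c, c_prev, h_prev = acts["tanh_c"][t], acts["c_prev"][t], acts["h_prev"][t]
        dh_new = dh * m
        dh_skip = dh * (1.0 - m)
        dc_new = dc * m + dh_new * o * (1.0 - tanh_c**2)
        dc_skip = dc * (1.0 - m)
        do = dh_new * tanh_c
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dAt = dA[t]
        dAt[:, :H] = di * i * (1.0 - i)
        dAt[:, H : 2 * H] = df * f * (1.0 - f)
        dAt[:, 2 * H : 3 * H] = dg * (1.0 - g**2)
        dAt[:, 3 * H :] = do * o * (1.0 - o)
        dWh += h_prev.T @ dAt
        dh = dh_skip + dAt @ WhT
        dc = dc_skip + dc_new * f

    dA_flat = dA.transpose(1, 0, 2).reshape(B * T, 4 * H)
    grads["Wx"] = Xc.reshape(B * T, D).T @ dA_flat
    grads["Wh"] = dWh
    grads["b"] = dA_flat.sum(axis=0)
    return loss, grads


class AdamState:
    """First/second-moment accumulators for Adam."""

    def __init__(self, params: LSTMParams, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, clip_norm: float = 5.0):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}


def adam_step(params: LSTMParams, grads: dict, state: AdamState) -> None:
    """One in-place Adam update with global-norm gradient clipping."""
    norm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads.values()))
    if state.clip_norm and norm > state.clip_norm:
        scale = DTYPE(state.clip_norm / norm)
        grads = {k: g * scale for k, g in grads.items()}
    state.t += 1
    bc1 = 1.0 - state.beta1**state.t
    bc2 = 1.0 - state.beta2**state.t
    for k, p in params.items():
        g = grads[k]
        state.m[k] = state.beta1 * state.m[k] + (1 - state.beta1) * g
        state.v[k] = state.beta2 * state.v[k] + (1 - state.beta2) * g**2
        m_hat = state.m[k] / bc1
        v_hat = state.v[k] / bc2
        p -= (state.lr * m_hat / (np.sqrt(v_hat) + state.eps)).astype(DTYPE)
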