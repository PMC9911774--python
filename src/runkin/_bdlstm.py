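"""A small bidirectional LSTM sequence-to-sequence regressor in NumPy.

Architecture (per 1-s window): sequence input -> bidirectional LSTM
(standard gate activations, hidden state per direction ``hidden_units``) ->
per-timestep fully connected layer with sigmoid activation -> linear
regression output (one value per timestep). Trained with mini-batch Adam on
mean squared error. Sizes here are tiny (tens of hidden units, 100-sample
windows), where a straightforward vectorised NumPy implementation is fast
and exactly reproducible under a fixed seed.

Gradients are computed by backpropagation through time; their correctness
is verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class BiLSTMRegressor:
    """Bidirectional LSTM with a sigmoid fully connected head and linear output."""

    def __init__(self, n_channels: int, hidden_units: int, fc_units: int,
                 seed: int) -> None:
        self.n_channels = n_channels
        self.hidden_units = hidden_units
        self.fc_units = fc_units
        rng = np.random.default_rng(seed)
        H, C, F = hidden_units, n_channels, fc_units
        self.params: dict[str, np.ndarray] = {}

        def init(shape, fan_in):
            s = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-s, s, size=shape)

        for d in ("f", "b"):  # forward / backward directions
            self.params[f"Wx_{d}"] = init((4 * H, C), C)
            self.params[f"Wh_{d}"] = init((4 * H, H), H)
            bias = np.zeros(4 * H)
            bias[H:2 * H] = 1.0  # forget-gate bias
            self.params[f"b_{d}"] = bias
        self.params["Wf"] = init((F, 2 * H), 2 * H)
        self.params["bf"] = np.zeros(F)
        self.params["Wo"] = init((1, F), F)
        self.params["bo"] = np.zeros(1)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward ------------------------------------------------------------

    def _lstm_pass(self, x: np.ndarray, d: str, reverse: bool):
        Wx, Wh, b = (self.params[f"Wx_{d}"], self.params[f"Wh_{d}"],
                     self.params[f"b_{d}"])
        if reverse:
            x = x[:, ::-1]
        B, T, _ = x.shape
        H = self.hidden_units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = x[:, t] @ Wx.T + h @ Wh.T + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            cache.append((x[:, t], h, c, i, f, g, o, tc))
            h = o * tc
            c = c_new
            hs[:, t] = h
        if reverse:
            hs = hs[:, ::-1]
        return hs, cache

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (batch, time, channels) -> predictions (batch, time)."""
        hs_f, cache_f = self._lstm_pass(x, "f", reverse=False)
        hs_b, cache_b = self._lstm_pass(x, "b", reverse=True)
        h_cat = np.concatenate([hs_f, hs_b], axis=2)          # (B, T, 2H)
        a1 = _sigmoid(h_cat @ self.params["Wf"].T + self.params["bf"])
        y = (a1 @ self.params["Wo"].T + self.params["bo"])[..., 0]
        if not want_cache:
            return y
        return y, {"x": x, "h_cat": h_cat, "a1": a1,
                   "cache_f": cache_f, "cache_b": cache_b}

    # -- backward -----------------------------------------------------------

    def _lstm_backward(self, dh_seq: np.ndarray, cache, d: str, reverse: bool,
                       grads: dict[str, np.ndarray]) -> None:
        Wh = self.params[f"Wh_{d}"]
        H = self.hidden_units
        if reverse:
            dh_seq = dh_seq[:, ::-1]
        B, T, _ = dh_seq.shape
        dWx = grads[f"Wx_{d}"]
        dWh = grads[f"Wh_{d}"]
        db = grads[f"b_{d}"]
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = dh_seq[:, t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g * g), do * o * (1 - o)], axis=1)
            dWx += dz.T @ x_t
            dWh += dz.T @ h_prev
            db += dz.sum(axis=0)
            dh_next = dz @ Wh
            dc_next = dc * f

    def backward(self, cache, dy: np.ndarray) -> dict[str, np.ndarray]:
        """dy: (batch, time) gradient of the loss w.r.t. predictions."""
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        a1, h_cat = cache["a1"], cache["h_cat"]
        B, T = dy.shape
        dyf = dy[..., None]                                   # (B, T, 1)
        a1_flat = a1.reshape(B * T, -1)
        grads["Wo"] += dyf.reshape(B * T, 1).T @ a1_flat
        grads["bo"] += dy.sum()
        da1 = dyf @ self.params["Wo"]                         # (B, T, F)
        dz1 = da1 * a1 * (1.0 - a1)
        dz1_flat = dz1.reshape(B * T, -1)
        grads["Wf"] += dz1_flat.T @ h_cat.reshape(B * T, -1)
        grads["bf"] += dz1_flat.sum(axis=0)
        dh_cat = dz1 @ self.params["Wf"]                      # (B, T, 2H)
        H = self.hidden_units
        self._lstm_backward(dh_cat[..., :H], cache["cache_f"], "f", False, grads)
        self._lstm_backward(dh_cat[..., H:], cache["cache_b"], "b", True, grads)
        return grads

    # -- optimisation -------------------------------------------------------

    def adam_step(self, grads: dict[str, np.ndarray], lr: float,
                  beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for k, p in self.params.items():
            g = grads[k]
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            m_hat = self._adam_m[k] / (1 - beta1 ** t)
            v_hat = self._adam_v[k] / (1 - beta2 ** t)
            p -= lr * m_hat / (np.sqrt(v_hat) + eps)

    def loss_and_grads(self, x: np.ndarray, target: np.ndarray
                       ) -> tuple[float, dict[str, np.ndarray]]:
        y, cache = self.forward(x, want_cache=True)
        diff = y - target
        loss = float(np.mean(diff * diff))
        dy = 2.0 * diff / diff.size
        return loss, self.backward(cache, dy)

    def fit(self, x: np.ndarray, target: np.ndarray, epochs: int,
            batch_size: int, lr: float, seed: int,
            callback=None) -> list[float]:
        """Mini-batch Adam training on MSE; returns the per-epoch mean loss."""
        rng = np.random.default_rng(seed)
        n = x.shape[0]
        history = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                loss, grads = self.loss_and_grads(x[idx], target[idx])
                self.adam_step(grads, lr)
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if callback is not None:
                callback(epoch, history[-1])
        return history

    # -- (de)serialisation ----------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=float).copy()
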