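"""A compact LSTM binary classifier on fixed-length feature vectors.

The recurrent base learner reads each molecule's feature vector as a short
sequence: two stacked LSTM layers (64 units each), dropout after each
recurrent layer, and a dense sigmoid head. Training minimizes binary
cross-entropy with Adam. Everything is plain numpy with exact
backpropagation-through-time; gradients are verified against central
differences in the test suite.

Input shaping (how a length-f vector becomes a sequence):

``chunked`` (default)
    Reshape to ``seq_len`` timesteps of ``ceil(f / seq_len)`` channels
    (zero-padded). Keeps the sequence reading of a fingerprint at a cost
    that scales with ``seq_len`` rather than ``f``.
``per_feature``
    One scalar per timestep (sequence length = f, channel 1).
``single``
    One timestep carrying the whole vector.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMClassifier:
    """Two-layer LSTM + sigmoid head with an sklearn-like fit/predict_proba.

    Parameters
    ----------
    units : int
        Hidden units per recurrent layer.
    n_layers : int
        Number of stacked LSTM layers.
    dropout : float
        Inverted-dropout rate applied to each recurrent layer's output
        sequence during training.
    learning_rate, epochs, batch_size :
        Adam step size and training schedule.
    input_shaping : {"chunked", "per_feature", "single"}
    seq_len : int
        Target timestep count for ``chunked`` shaping.
    seed : int
        Seeds parameter init, batch shuffling and dropout masks.
    """

    def __init__(
        self,
        units: int = 64,
        n_layers: int = 2,
        dropout: float = 0.2,
        learning_rate: float = 0.001,
        epochs: int = 10,
        batch_size: int = 128,
        input_shaping: str = "chunked",
        seq_len: int = 32,
        seed: int = 0,
    ):
        if not 0 <= dropout < 1:
            raise ConfigError("dropout must lie in [0, 1)")
        if input_shaping not in ("chunked", "per_feature", "single"):
            raise ConfigError(f"unknown input_shaping {input_shaping!r}")
        if units < 1 or n_layers < 1 or epochs < 1 or batch_size < 1 or seq_len < 1:
            raise ConfigError("units, n_layers, epochs, batch_size, seq_len must be >= 1")
        self.units = units
        self.n_layers = n_layers
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.input_shaping = input_shaping
        self.seq_len = seq_len
        self.seed = seed
        self.classes_ = np.array([0, 1])
        self.loss_history_: list[float] = []

    # ------------------------------------------------------------------ setup
    def _shape_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n, f = X.shape
        if self.input_shaping == "per_feature":
            return X.reshape(n, f, 1)
        if self.input_shaping == "single":
            return X.reshape(n, 1, f)
        t = min(self.seq_len, f)
        ch = int(np.ceil(f / t))
        pad = t * ch - f
        if pad:
            X = np.hstack([X, np.zeros((n, pad))])
        return X.reshape(n, t, ch)

    def _init_params(self, n_channels: int, rng: np.random.Generator) -> None:
        H = self.units
        self.params_ = {}
        d = n_channels
        for layer in range(self.n_layers):
            scale_w = np.sqrt(6.0 / (d + 4 * H))
            scale_u = np.sqrt(6.0 / (H + 4 * H))
            self.params_[f"W{layer}"] = rng.uniform(-scale_w, scale_w, (d, 4 * H))
            self.params_[f"U{layer}"] = rng.uniform(-scale_u, scale_u, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H : 2 * H] = 1.0  # forget-gate bias
            self.params_[f"b{layer}"] = b
            d = H
        self.params_["w_out"] = rng.uniform(-np.sqrt(6.0 / (H + 1)), np.sqrt(6.0 / (H + 1)), H)
        self.params_["b_out"] = np.zeros(1)

    # ---------------------------------------------------------------- forward
    def _lstm_forward(self, x: np.ndarray, layer: int):
        """x: (B, T, D) -> output sequence (B, T, H) plus BPTT cache."""
        W, U, b = (self.params_[f"{k}{layer}"] for k in "WUb")
        B, T, _ = x.shape
        H = self.units
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        h_seq = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = x[:, t] @ W + h @ U + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            cache.append((x[:, t], h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
            h_seq[:, t] = h
        return h_seq, cache

    def _lstm_backward(self, dh_seq: np.ndarray, cache, layer: int):
        """Gradient of the loss wrt this layer's params and input sequence."""
        W, U = self.params_[f"W{layer}"], self.params_[f"U{layer}"]
        B, T, H = dh_seq.shape
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros(4 * H)
        dx_seq = np.empty((B, T, W.shape[0]))
        dh_carry = np.zeros((B, H))
        dc_carry = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, tanh_c = cache[t]
            dh = dh_seq[:, t] + dh_carry
            do = dh * tanh_c
            dc = dh * o * (1 - tanh_c**2) + dc_carry
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.hstack(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)]
            )
            dW += x_t.T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx_seq[:, t] = dz @ W.T
            dh_carry = dz @ U.T
            dc_carry = dc * f
        return dW, dU, db, dx_seq

    def _loss_and_grads(self, xb: np.ndarray, yb: np.ndarray, rng: np.random.Generator | None):
        """Mean BCE loss and exact parameter gradients for one batch.

        ``rng`` draws dropout masks; None disables dropout (evaluation mode).
        """
        B = xb.shape[0]
        caches, masks, layer_out = [], [], xb
        for layer in range(self.n_layers):
            h_seq, cache = self._lstm_forward(layer_out, layer)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h_seq.shape) >= self.dropout) / (1 - self.dropout)
            else:
                mask = np.ones_like(h_seq)
            caches.append(cache)
            masks.append(mask)
            layer_out = h_seq * mask
        last_h = layer_out[:, -1]
        logits = last_h @ self.params_["w_out"] + self.params_["b_out"][0]
        p = _sigmoid(logits)
        eps = 1e-12
        loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))

        grads = {}
        dlogits = (p - yb) / B
        grads["w_out"] = last_h.T @ dlogits
        grads["b_out"] = np.array([dlogits.sum()])
        dh_seq = np.zeros_like(layer_out)
        dh_seq[:, -1] = np.outer(dlogits, self.params_["w_out"])
        for layer in reversed(range(self.n_layers)):
            dh_seq = dh_seq * masks[layer]
            dW, dU, db, dh_seq = self._lstm_backward(dh_seq, caches[layer], layer)
            grads[f"W{layer}"] = dW
            grads[f"U{layer}"] = dU
            grads[f"b{layer}"] = db
        return loss, grads

    # --------------------------------------------------------------- training
    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        Xs = self._shape_input(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if Xs.shape[0] != y.shape[0]:
            raise ValueError("X and y row counts differ")
        rng = np.random.default_rng(self.seed)
        self._init_params(Xs.shape[2], rng)

        adam_m = {k: np.zeros_like(v) for k, v in self.params_.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params_.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = Xs.shape[0]
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_losses = []
            for start in range(0, n, self.batch_size):
                batch = order[start : start + self.batch_size]
                loss, grads = self._loss_and_grads(Xs[batch], y[batch], rng)
                epoch_losses.append(loss)
                step += 1
                for k, g in grads.items():
                    adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * g
                    adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * g**2
                    m_hat = adam_m[k] / (1 - beta1**step)
                    v_hat = adam_v[k] / (1 - beta2**step)
                    self.params_[k] -= self.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
            self.loss_history_.append(float(np.mean(epoch_losses)))
        return self

    # -------------------------------------------------------------- inference
    def _forward_proba(self, Xs: np.ndarray) -> np.ndarray:
        layer_out = Xs
        for layer in range(self.n_layers):
            layer_out, _ = self._lstm_forward(layer_out, layer)
        logits = layer_out[:, -1] @ self.params_["w_out"] + self.params_["b_out"][0]
        return _sigmoid(logits)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-probability matrix (n, 2), columns ordered [P(0), P(1)]."""
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")
        p1 = self._forward_proba(self._shape_input(np.asarray(X, dtype=float)))
        return np.column_stack([1 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
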