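"""Minimal bidirectional-LSTM sequence classifier in pure numpy.

Architecture: two stacked bidirectional LSTM layers (64 units each by
default; the first emits the full hidden sequence, the second only its
final states), followed by a 2-way linear readout with softmax. Training
uses Adam with global-norm gradient clipping. Gradients are computed by
hand-written backpropagation through time; a finite-difference check
lives in the test suite.

All state is plain numpy arrays, so models serialize to ``.npz``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BiLSTMClassifier"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clip rather than branch: |z| > 30 saturates past float32 resolution
    return 1.0 / (1.0 + np.exp(-np.clip(z, -30.0, 30.0)))


def _init_lstm(rng: np.random.Generator, d: int, h: int) -> dict[str, np.ndarray]:
    s_w = np.sqrt(6.0 / (d + 4 * h))
    s_u = np.sqrt(6.0 / (h + 4 * h))
    b = np.zeros(4 * h)
    b[h : 2 * h] = 1.0  # forget-gate bias (gate order: i, f, o, g)
    return {
        "W": rng.uniform(-s_w, s_w, size=(d, 4 * h)),
        "U": rng.uniform(-s_u, s_u, size=(h, 4 * h)),
        "b": b,
    }


def _lstm_forward(x: np.ndarray, p: dict[str, np.ndarray]):
    """x: (B, T, D) -> hidden sequence (B, T, H) plus backprop cache."""
    B, T, _ = x.shape
    H = p["U"].shape[0]
    h = np.zeros((B, H), dtype=x.dtype)
    c = np.zeros((B, H), dtype=x.dtype)
    hs = np.zeros((B, T, H), dtype=x.dtype)
    cache = []
    xW = x @ p["W"] + p["b"]  # precompute input contributions
    for t in range(T):
        z = xW[:, t] + h @ p["U"]
        sig = _sigmoid(z[:, : 3 * H])
        i = sig[:, :H]
        f = sig[:, H : 2 * H]
        o = sig[:, 2 * H :]
        g = np.tanh(z[:, 3 * H :])
        c_prev = c
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h_prev = h
        h = o * tc
        hs[:, t] = h
        cache.append((i, f, g, o, c_prev, tc, h_prev))
    return hs, cache


def _lstm_backward(dhs: np.ndarray, x: np.ndarray, cache, p):
    """dhs: (B, T, H) upstream gradient on the hidden sequence."""
    B, T, D = x.shape
    H = p["U"].shape[0]
    dW = np.zeros_like(p["W"])
    dU = np.zeros_like(p["U"])
    db = np.zeros_like(p["b"])
    dx = np.zeros_like(x)
    dh_next = np.zeros((B, H), dtype=x.dtype)
    dc_next = np.zeros((B, H), dtype=x.dtype)
    for t in range(T - 1, -1, -1):
        i, f, g, o, c_prev, tc, h_prev = cache[t]
        dh = dhs[:, t] + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        dc_next = dc * f
        dz = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g * g),
            ],
            axis=1,
        )
        dW += x[:, t].T @ dz
        dU += h_prev.T @ dz
        db += dz.sum(axis=0)
        dh_next = dz @ p["U"].T
        dx[:, t] = dz @ p["W"].T
    return dx, {"W": dW, "U": dU, "b": db}


class BiLSTMClassifier:
    """Two stacked bidirectional LSTM layers and a softmax readout."""

    PARAM_KEYS = ("l1f", "l1b", "l2f", "l2b")

    def __init__(
        self,
        input_size: int = 1,
        hidden: int = 64,
        seed: int = 0,
        dtype=np.float32,
    ):
        self.input_size = input_size
        self.hidden = hidden
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        h = hidden
        self.params: dict[str, dict[str, np.ndarray]] = {
            "l1f": _init_lstm(rng, input_size, h),
            "l1b": _init_lstm(rng, input_size, h),
            "l2f": _init_lstm(rng, 2 * h, h),
            "l2b": _init_lstm(rng, 2 * h, h),
        }
        for d in self.params.values():
            for k in d:
                d[k] = d[k].astype(self.dtype)
        s = np.sqrt(6.0 / (2 * h + 2))
        self.Wout = rng.uniform(-s, s, size=(2 * h, 2)).astype(self.dtype)
        self.bout = np.zeros(2, dtype=self.dtype)

    # ------------------------------------------------------------------ #

    def _forward(self, x: np.ndarray):
        xr = x[:, ::-1]
        h1f, c1f = _lstm_forward(x, self.params["l1f"])
        h1b, c1b = _lstm_forward(xr, self.params["l1b"])
        h1 = np.concatenate([h1f, h1b[:, ::-1]], axis=2)
        h1r = h1[:, ::-1]
        h2f, c2f = _lstm_forward(h1, self.params["l2f"])
        h2b, c2b = _lstm_forward(h1r, self.params["l2b"])
        feat = np.concatenate([h2f[:, -1], h2b[:, -1]], axis=1)
        logits = feat @ self.Wout + self.bout
        logits = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        probs = ez / ez.sum(axis=1, keepdims=True)
        cache = (x, xr, c1f, c1b, h1, h1r, c2f, c2b, feat)
        return probs, cache

    def predict_proba(self, x: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """P(class) for x of shape (B, T) or (B, T, input_size)."""
        x = self._as3d(x)
        out = np.empty((x.shape[0], 2))
        for i in range(0, x.shape[0], chunk):
            out[i : i + chunk] = self._forward(x[i : i + chunk])[0]
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def _as3d(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 2:
            x = x[:, :, None]
        return x

    # ------------------------------------------------------------------ #

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and gradients for a minibatch."""
        x = self._as3d(x)
        B = x.shape[0]
        probs, cache = self._forward(x)
        (x3, xr, c1f, c1b, h1, h1r, c2f, c2b, feat) = cache
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(B), y] + eps))

        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads: dict[str, object] = {
            "Wout": feat.T @ dlogits,
            "bout": dlogits.sum(axis=0),
        }
        dfeat = dlogits @ self.Wout.T
        H = self.hidden
        T = x.shape[1]

        dh2f = np.zeros((B, T, H), dtype=self.dtype)
        dh2f[:, -1] = dfeat[:, :H]
        dh2b = np.zeros((B, T, H), dtype=self.dtype)
        dh2b[:, -1] = dfeat[:, H:]
        dh1_a, g2f = _lstm_backward(dh2f, h1, c2f, self.params["l2f"])
        dh1r_b, g2b = _lstm_backward(dh2b, h1r, c2b, self.params["l2b"])
        dh1 = dh1_a + dh1r_b[:, ::-1]

        _, g1f = _lstm_backward(dh1[:, :, :H], x3, c1f, self.params["l1f"])
        _, g1b = _lstm_backward(dh1[:, ::-1, H:], xr, c1b, self.params["l1b"])
        grads["l1f"] = g1f
        grads["l1b"] = g1b
        grads["l2f"] = g2f
        grads["l2b"] = g2b
        acc = float(np.mean(probs.argmax(axis=1) == y))
        return loss, grads, acc

    # ------------------------------------------------------------------ #

    def _flat_params(self):
        for k in self.PARAM_KEYS:
            for name in ("W", "U", "b"):
                yield f"{k}.{name}", self.params[k][name]
        yield "Wout", self.Wout
        yield "bout", self.bout

    @staticmethod
    def _flat_grads(grads):
        for k in BiLSTMClassifier.PARAM_KEYS:
            for name in ("W", "U", "b"):
                yield f"{k}.{name}", grads[k][name]
        yield "Wout", grads["Wout"]
        yield "bout", grads["bout"]

    def fit_minibatches(
        self,
        x: np.ndarray,
        y: np.ndarray,
        *,
        max_epochs: int = 200,
        batch_size: int = 256,
        learning_rate: float = 0.005,
        gradient_clip: float = 1.0,
        lr_decay: float = 1.0,
        lr_decay_every: int = 15,
        seed: int = 0,
        stop_when=None,
        callback=None,
    ):
        """Adam training loop; returns per-epoch (loss, accuracy) history.

        ``stop_when(epoch, loss, acc) -> bool`` allows early stopping;
        ``callback`` receives the same tuple every epoch. The learning
        rate is multiplied by ``lr_decay`` every ``lr_decay_every``
        epochs (stepped decay helps memorize rare sequence variants
        after the bulk of the loss has been fit).
        """
        x = self._as3d(x)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self._flat_params()}
        v2 = {k: np.zeros_like(vv) for k, vv in self._flat_params()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
        history = []
        for epoch in range(max_epochs):
            lr = learning_rate * lr_decay ** (epoch // lr_decay_every)
            order = rng.permutation(x.shape[0])
            ep_loss = 0.0
            ep_hits = 0
            for start in range(0, x.shape[0], batch_size):
                idx = order[start : start + batch_size]
                loss, grads, acc = self.loss_and_grads(x[idx], y[idx])
                flat = dict(self._flat_grads(grads))
                norm = np.sqrt(sum(float(np.sum(g * g)) for g in flat.values()))
                if gradient_clip and norm > gradient_clip:
                    for g in flat.values():
                        g *= gradient_clip / norm
                step += 1
                for (k, p), g in zip(self._flat_params(), flat.values()):
                    m[k] = b1 * m[k] + (1 - b1) * g
                    v2[k] = b2 * v2[k] + (1 - b2) * g * g
                    mh = m[k] / (1 - b1**step)
                    vh = v2[k] / (1 - b2**step)
                    p -= lr * mh / (np.sqrt(vh) + eps)
                ep_loss += loss * idx.size
                ep_hits += int(round(acc * idx.size))
            ep_loss /= x.shape[0]
            ep_acc = ep_hits / x.shape[0]
            history.append((ep_loss, ep_acc))
            if callback is not None:
                callback(epoch, ep_loss, ep_acc)
            if stop_when is not None and stop_when(epoch, ep_loss, ep_acc):
                break
        return history

    # ------------------------------------------------------------------ #

    def save(self, path) -> None:
        arrays = {k: v for k, v in self._flat_params()}
        arrays["_meta"] = np.array([self.input_size, self.hidden])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "BiLSTMClassifier":
        with np.load(path) as data:
            input_size, hidden = (int(v) for v in data["_meta"])
            model = cls(input_size=input_size, hidden=hidden, seed=0)
            model.dtype = data["Wout"].dtype
            for k in cls.PARAM_KEYS:
                for name in ("W", "U", "b"):
                    model.params[k][name] = data[f"{k}.{name}"]
            model.Wout = data["Wout"]
            model.bout = data["bout"]
        return model
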