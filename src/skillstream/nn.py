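"""Sequence-to-sequence LSTM regression engine.

A deliberately minimal recurrent network — sequence input, two unidirectional
LSTM layers each followed by dropout, a fully connected layer, and a
mean-squared-error regression head — trained with Adam under a step-decay
learning-rate schedule.  Every timestep of the input sequence carries its own
regression target, and the loss pools squared errors over all (unpadded)
timesteps of all sequences in a minibatch.

Implemented directly in NumPy (forward pass and full backpropagation through
time) because the networks are tiny — hidden width is the feature count plus
one — and a hand-rolled cell keeps the package dependency-light and exactly
reproducible.  Gate algebra uses the standard LSTM equations with gate order
(input, forget, cell, output) and forget-gate bias initialized to 1.
Variable-length sequences are padded at the end and padded steps are masked
out of the loss.  The analytic gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidArgumentError, TrainingDivergedError

__all__ = ["TrainingSchedule", "LSTMRegressor", "rmse", "learning_rate_at"]


def rmse(predictions, targets) -> float:
    """Root-mean-squared error pooled over all timesteps."""
    p = np.asarray(predictions, float).ravel()
    t = np.asarray(targets, float).ravel()
    if p.size == 0 or t.size == 0:
        raise InvalidArgumentError("rmse of empty input is undefined")
    if p.size != t.size:
        raise InvalidArgumentError(f"length mismatch: {p.size} vs {t.size}")
    return float(np.sqrt(np.mean((p - t) ** 2)))


@dataclass(frozen=True)
class TrainingSchedule:
    """Adam optimizer schedule: step-decay learning rate, shuffling each epoch.

    Defaults: initial rate 1e-3 decayed by x0.1 every 25 epochs, 1000
    epochs.  Tests and desk-scale runs pass a reduced epoch count.
    """

    initial_lr: float = 1e-3
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 25
    epochs: int = 1000
    minibatch_size: int = 18
    seed: int = 0
    grad_clip: float | None = None  # max gradient norm; None disables

    def validate(self) -> None:
        if (self.initial_lr <= 0 or self.lr_decay_factor <= 0
                or self.lr_decay_every < 1 or self.epochs < 1
                or self.minibatch_size < 1):
            raise InvalidArgumentError("all schedule parameters must be positive")


def learning_rate_at(epoch: int, schedule: TrainingSchedule) -> float:
    """lr(epoch) = initial * factor^floor((epoch-1)/every), epoch 1-based."""
    if epoch < 1:
        raise InvalidArgumentError("epochs are 1-based")
    return schedule.initial_lr * schedule.lr_decay_factor ** (
        (epoch - 1) // schedule.lr_decay_every
    )


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# Compiled recurrence kernels.  The cell is tiny (17 units), so per-step
# Python overhead dominates a pure-NumPy loop; numba removes it.  The NumPy
# path below remains as a functionally identical fallback and as the
# reference the gradient-check test exercises when numba is absent.
# ---------------------------------------------------------------------------
try:  # pragma: no cover - environment dependent
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(fn):
            return fn

        return wrap


@njit(fastmath=False)
def _fwd_kernel(Zx, Wh, H, Ig, Fg, Gg, Og, Cs, TC):  # pragma: no cover - compiled
    B, T, H4 = Zx.shape
    hu = H4 // 4
    h = np.zeros((B, hu))
    c = np.zeros((B, hu))
    z = np.empty((B, H4))
    for t in range(T):
        for b in range(B):
            for k in range(H4):
                acc = Zx[b, t, k]
                for j in range(hu):
                    acc += h[b, j] * Wh[j, k]
                z[b, k] = acc
        for b in range(B):
            for j in range(hu):
                zi, zf = z[b, j], z[b, hu + j]
                zg, zo = z[b, 2 * hu + j], z[b, 3 * hu + j]
                i = 1.0 / (1.0 + np.exp(-zi)) if zi >= 0 else (
                    np.exp(zi) / (1.0 + np.exp(zi)))
                f = 1.0 / (1.0 + np.exp(-zf)) if zf >= 0 else (
                    np.exp(zf) / (1.0 + np.exp(zf)))
                o = 1.0 / (1.0 + np.exp(-zo)) if zo >= 0 else (
                    np.exp(zo) / (1.0 + np.exp(zo)))
                g = np.tanh(zg)
                cv = f * c[b, j] + i * g
                tc = np.tanh(cv)
                hv = o * tc
                c[b, j] = cv
                h[b, j] = hv
                Ig[b, t, j], Fg[b, t, j], Gg[b, t, j], Og[b, t, j] = i, f, g, o
                Cs[b, t, j], TC[b, t, j] = cv, tc
                H[b, t, j] = hv


@njit(fastmath=False)
def _bwd_kernel(dH, Wh, H, Ig, Fg, Gg, Og, Cs, TC, dZ, dWh):  # pragma: no cover
    B, T, hu = dH.shape
    H4 = 4 * hu
    dh_rec = np.zeros((B, hu))
    dc = np.zeros((B, hu))
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for j in range(hu):
                i, f, g = Ig[b, t, j], Fg[b, t, j], Gg[b, t, j]
                o, tc = Og[b, t, j], TC[b, t, j]
                c_prev = Cs[b, t - 1, j] if t > 0 else 0.0
                dh = dH[b, t, j] + dh_rec[b, j]
                do = dh * tc
                dcv = dc[b, j] + dh * o * (1.0 - tc * tc)
                dZ[b, t, j] = (dcv * g) * i * (1.0 - i)
                dZ[b, t, hu + j] = (dcv * c_prev) * f * (1.0 - f)
                dZ[b, t, 2 * hu + j] = (dcv * i) * (1.0 - g * g)
                dZ[b, t, 3 * hu + j] = do * o * (1.0 - o)
                dc[b, j] = dcv * f
        for b in range(B):
            for j in range(hu):
                acc = 0.0
                for k in range(H4):
                    acc += dZ[b, t, k] * Wh[j, k]
                dh_rec[b, j] = acc
        if t > 0:
            for j in range(hu):
                for k in range(H4):
                    acc = 0.0
                    for b in range(B):
                        acc += H[b, t - 1, j] * dZ[b, t, k]
                    dWh[j, k] += acc


class _LSTMLayer:
    """One unidirectional LSTM layer with cached activations for BPTT."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator):
        h = n_units
        bound = np.sqrt(6.0 / (n_in + h))
        self.Wx = rng.uniform(-bound, bound, (n_in, 4 * h))
        bound_r = np.sqrt(6.0 / (2 * h))
        self.Wh = rng.uniform(-bound_r, bound_r, (h, 4 * h))
        self.b = np.zeros(4 * h)
        self.b[h:2 * h] = 1.0  # forget gate bias
        self.n_units = h

    def params(self):
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b}

    def forward(self, X: np.ndarray, cache: bool = False):
        """X: (B, T, n_in) -> H: (B, T, units).

        The input projection X @ Wx is hoisted out of the time loop; only the
        recurrent projection runs per step.
        """
        B, T, _ = X.shape
        h_units = self.n_units
        H = np.empty((B, T, h_units))
        h = np.zeros((B, h_units))
        c = np.zeros((B, h_units))
        Zx = X.reshape(B * T, -1) @ self.Wx
        Zx = np.ascontiguousarray(Zx.reshape(B, T, 4 * h_units) + self.b)
        if _HAVE_NUMBA:
            Ig = np.empty((B, T, h_units))
            Fg = np.empty((B, T, h_units))
            Gg = np.empty((B, T, h_units))
            Og = np.empty((B, T, h_units))
            Cs = np.empty((B, T, h_units))
            TC = np.empty((B, T, h_units))
            _fwd_kernel(Zx, self.Wh, H, Ig, Fg, Gg, Og, Cs, TC)
            if cache:
                self._X = X
                self._i, self._f, self._g = Ig, Fg, Gg
                self._o, self._c, self._tc = Og, Cs, TC
            self._H = H if cache else None
            return H
        if cache:
            self._X = X
            self._i = np.empty((B, T, h_units))
            self._f = np.empty((B, T, h_units))
            self._g = np.empty((B, T, h_units))
            self._o = np.empty((B, T, h_units))
            self._c = np.empty((B, T, h_units))
            self._tc = np.empty((B, T, h_units))
        for t in range(T):
            z = Zx[:, t] + h @ self.Wh
            i = _sigmoid(z[:, :h_units])
            f = _sigmoid(z[:, h_units:2 * h_units])
            g = np.tanh(z[:, 2 * h_units:3 * h_units])
            o = _sigmoid(z[:, 3 * h_units:])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            H[:, t] = h
            if cache:
                self._i[:, t], self._f[:, t], self._g[:, t] = i, f, g
                self._o[:, t], self._c[:, t], self._tc[:, t] = o, c, tc
        self._H = H if cache else None
        return H

    def backward(self, dH: np.ndarray):
        """dH: (B, T, units) gradient wrt outputs; returns (dX, grads)."""
        X = self._X
        B, T, n_in = X.shape
        hu = self.n_units
        dWh = np.zeros_like(self.Wh)
        dZ = np.empty((B, T, 4 * hu))
        if _HAVE_NUMBA:
            dH = np.ascontiguousarray(dH)
            _bwd_kernel(dH, self.Wh, self._H, self._i, self._f, self._g,
                        self._o, self._c, self._tc, dZ, dWh)
            flat_dZ = dZ.reshape(B * T, 4 * hu)
            dWx = X.reshape(B * T, n_in).T @ flat_dZ
            db = flat_dZ.sum(axis=0)
            dX = (flat_dZ @ self.Wx.T).reshape(B, T, n_in)
            return dX, {"Wx": dWx, "Wh": dWh, "b": db}
        dh_rec = np.zeros((B, hu))
        dc = np.zeros((B, hu))
        zeros = np.zeros((B, hu))
        for t in range(T - 1, -1, -1):
            i, f, g = self._i[:, t], self._f[:, t], self._g[:, t]
            o, c, tc = self._o[:, t], self._c[:, t], self._tc[:, t]
            c_prev = self._c[:, t - 1] if t > 0 else zeros
            h_prev = self._H[:, t - 1] if t > 0 else zeros
            dh = dH[:, t] + dh_rec
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            dz = dZ[:, t]
            dz[:, :hu] = (dc * g) * i * (1.0 - i)
            dz[:, hu:2 * hu] = (dc * c_prev) * f * (1.0 - f)
            dz[:, 2 * hu:3 * hu] = (dc * i) * (1.0 - g * g)
            dz[:, 3 * hu:] = do * o * (1.0 - o)
            dWh += h_prev.T @ dz
            dh_rec = dz @ self.Wh.T
            dc = dc * f
        flat_dZ = dZ.reshape(B * T, 4 * hu)
        dWx = X.reshape(B * T, n_in).T @ flat_dZ
        db = flat_dZ.sum(axis=0)
        dX = (flat_dZ @ self.Wx.T).reshape(B, T, n_in)
        return dX, {"Wx": dWx, "Wh": dWh, "b": db}


class LSTMRegressor:
    """Two-layer LSTM with dropout and a scalar output per timestep."""

    def __init__(self, n_features: int, hidden_units: int,
                 dropout_rate: float = 0.2, seed: int = 0):
        if n_features < 1 or hidden_units < 1:
            raise InvalidArgumentError("n_features and hidden_units must be >= 1")
        if not (0.0 <= dropout_rate < 1.0):
            raise InvalidArgumentError("dropout_rate must lie in [0, 1)")
        self.n_features = n_features
        self.hidden_units = hidden_units
        self.dropout_rate = dropout_rate
        rng = np.random.default_rng(seed)
        self.lstm1 = _LSTMLayer(n_features, hidden_units, rng)
        self.lstm2 = _LSTMLayer(hidden_units, hidden_units, rng)
        bound = np.sqrt(6.0 / (hidden_units + 1))
        self.Wfc = rng.uniform(-bound, bound, (hidden_units, 1))
        self.bfc = np.zeros(1)

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for tag, layer in (("l1", self.lstm1), ("l2", self.lstm2)):
            for k, v in layer.params().items():
                out[f"{tag}.{k}"] = v
        out["fc.W"] = self.Wfc
        out["fc.b"] = self.bfc
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for k, v in self.parameters().items():
            v[...] = params[k]

    # -- forward / backward -------------------------------------------------
    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None, cache: bool = False):
        """X: (B, T, F) -> predictions (B, T)."""
        H1 = self.lstm1.forward(X, cache=cache)
        if training and self.dropout_rate > 0.0:
            keep = 1.0 - self.dropout_rate
            m1 = (rng.uniform(size=H1.shape) < keep) / keep
            m2_shape = (H1.shape[0], H1.shape[1], self.hidden_units)
            m2 = (rng.uniform(size=m2_shape) < keep) / keep
        else:
            m1 = m2 = None
        D1 = H1 * m1 if m1 is not None else H1
        H2 = self.lstm2.forward(D1, cache=cache)
        D2 = H2 * m2 if m2 is not None else H2
        Y = (D2 @ self.Wfc)[..., 0] + self.bfc[0]
        if cache:
            self._m1, self._m2, self._D2 = m1, m2, D2
        return Y

    def loss_and_grads(self, X, targets, mask, rng):
        """Masked MSE loss and gradients for one minibatch.

        Returns (sse, n_valid, grads) where loss = sse / n_valid.
        """
        Y = self.forward(X, training=True, rng=rng, cache=True)
        resid = (Y - targets) * mask
        sse = float(np.sum(resid**2))
        n_valid = float(np.sum(mask))
        dY = 2.0 * resid / n_valid  # gradient of mean squared error
        dD2 = dY[..., None] * self.Wfc[:, 0]
        dWfc = np.einsum("bth,bt->h", self._D2, dY)[:, None]
        dbfc = np.array([dY.sum()])
        dH2 = dD2 * self._m2 if self._m2 is not None else dD2
        dD1, g2 = self.lstm2.backward(dH2)
        dH1 = dD1 * self._m1 if self._m1 is not None else dD1
        _, g1 = self.lstm1.backward(dH1)
        grads = {f"l1.{k}": v for k, v in g1.items()}
        grads.update({f"l2.{k}": v for k, v in g2.items()})
        grads["fc.W"] = dWfc
        grads["fc.b"] = dbfc
        return sse, n_valid, grads

    def predict(self, x: np.ndarray) -> np.ndarray:
        """x: (T, F) single sequence -> (T,) predictions (no dropout)."""
        return self.forward(x[None, :, :], training=False)[0]

    # -- training -----------------------------------------------------------
    def fit_sequences(
        self,
        train: list[tuple[np.ndarray, np.ndarray]],
        schedule: TrainingSchedule,
        validation: list[tuple[np.ndarray, np.ndarray]] | None = None,
    ) -> dict[str, list[float]]:
        """Train on (sequence, target) pairs; returns per-epoch RMSE history.

        Train RMSE is pooled from the minibatch losses of the epoch (the
        usual running-training-loss convention); validation RMSE is computed
        with dropout off after each epoch.
        """
        schedule.validate()
        if not train:
            raise InvalidArgumentError("empty training set")
        rng = np.random.default_rng(schedule.seed)
        params = self.parameters()
        m_adam = {k: np.zeros_like(v) for k, v in params.items()}
        v_adam = {k: np.zeros_like(v) for k, v in params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        history: dict[str, list[float]] = {"train": [], "validation": []}
        idx = np.arange(len(train))
        mb = schedule.minibatch_size
        for epoch in range(1, schedule.epochs + 1):
            lr = learning_rate_at(epoch, schedule)
            rng.shuffle(idx)
            sse_sum = 0.0
            n_sum = 0.0
            for start in range(0, len(idx), mb):
                batch = [train[j] for j in idx[start:start + mb]]
                X, tgt, mask = _pad_batch(batch)
                sse, n_valid, grads = self.loss_and_grads(X, tgt, mask, rng)
                if not np.isfinite(sse):
                    raise TrainingDivergedError(epoch)
                sse_sum += sse
                n_sum += n_valid
                if schedule.grad_clip is not None:
                    norm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
                    if norm > schedule.grad_clip:
                        scale = schedule.grad_clip / norm
                        for g in grads.values():
                            g *= scale
                step += 1
                bc1 = 1.0 - beta1**step
                bc2 = 1.0 - beta2**step
                for k, p in params.items():
                    g = grads[k]
                    m_adam[k] = beta1 * m_adam[k] + (1 - beta1) * g
                    v_adam[k] = beta2 * v_adam[k] + (1 - beta2) * g * g
                    p -= lr * (m_adam[k] / bc1) / (np.sqrt(v_adam[k] / bc2) + eps)
            history["train"].append(float(np.sqrt(sse_sum / n_sum)))
            if validation:
                history["validation"].append(self.evaluate(validation))
            else:
                history["validation"].append(float("nan"))
        return history

    def evaluate(self, pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
        """Pooled RMSE over sequences, dropout off."""
        sse = 0.0
        n = 0
        for x, y in pairs:
            pred = self.predict(x)
            sse += float(np.sum((pred - y) ** 2))
            n += y.size
        if n == 0:
            raise InvalidArgumentError("cannot evaluate on an empty set")
        return float(np.sqrt(sse / n))

    # -- serialization ------------------------------------------------------
    def weights_to_dict(self) -> dict:
        return {k: v.tolist() for k, v in self.parameters().items()}

    @classmethod
    def from_weights(cls, n_features: int, hidden_units: int, dropout_rate: float,
                     weights: dict) -> "LSTMRegressor":
        model = cls(n_features, hidden_units, dropout_rate, seed=0)
        model.set_parameters({k: np.asarray(v, float) for k, v in weights.items()})
        return model


def _pad_batch(batch: list[tuple[np.ndarray, np.ndarray]]):
    """End-pad sequences to the batch maximum; mask marks real timesteps."""
    B = len(batch)
    T = max(x.shape[0] for x, _ in batch)
    F = batch[0][0].shape[1]
    X = np.zeros((B, T, F))
    tgt = np.zeros((B, T))
    mask = np.zeros((B, T))
    for b, (x, y) in enumerate(batch):
        n = x.shape[0]
        X[b, :n] = x
        tgt[b, :n] = y
        mask[b, :n] = 1.0
    return X, tgt, mask
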