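"""Minimal recurrent neural networks (simple RNN and LSTM) in numpy.

The imputation study needs two small fixed architectures — a stacked LSTM
(64 → 32 recurrent units, 64-unit ReLU dense head) and a stacked simple
RNN with sigmoid activations (128 → 64 recurrent units, 128-unit ReLU
head) — trained with mean-squared-error loss and the Adam optimizer for
one-step-ahead prediction on 48-hour windows.  The networks here implement
exactly that: forward pass, full backpropagation through time, Adam with
minibatches, and optional early stopping on a held-out split.  Everything
is seeded and pure numpy, so results are reproducible run to run.

Gradients are exact (verified against central finite differences in the
test suite), not approximated.
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


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class SimpleRNNLayer:
    """Elman recurrent layer: h_t = act(x_t W + h_{t-1} U + b)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator,
                 activation: str = "sigmoid", return_sequences: bool = False):
        self.n_in, self.n_units = n_in, n_units
        self.activation = activation
        self.return_sequences = return_sequences
        self.W = _glorot(rng, n_in, n_units)
        self.U = _glorot(rng, n_units, n_units)
        self.b = np.zeros(n_units)

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        H = np.zeros((B, T + 1, self.n_units))
        for t in range(T):
            z = X[:, t] @ self.W + H[:, t] @ self.U + self.b
            H[:, t + 1] = _sigmoid(z) if self.activation == "sigmoid" else np.tanh(z)
        self._X, self._H = X, H
        return H[:, 1:] if self.return_sequences else H[:, -1]

    def backward(self, dY: np.ndarray):
        X, H = self._X, self._H
        B, T, _ = X.shape
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        carry = np.zeros((B, self.n_units))
        for t in range(T - 1, -1, -1):
            dh = carry.copy()
            if self.return_sequences:
                dh += dY[:, t]
            elif t == T - 1:
                dh += dY
            h = H[:, t + 1]
            if self.activation == "sigmoid":
                dz = dh * h * (1.0 - h)
            else:
                dz = dh * (1.0 - h * h)
            dW += X[:, t].T @ dz
            dU += H[:, t].T @ dz
            db += dz.sum(axis=0)
            carry = dz @ self.U.T
            dX[:, t] = dz @ self.W.T
        self._grads = [dW, dU, db]
        return dX


class LSTMLayer:
    """Standard LSTM with input/forget/output gates and tanh squashing.

    Gate pre-activations are packed as [i | f | o | g] columns of one
    weight matrix; the forget-gate bias starts at 1 (the usual trick to
    keep early gradients flowing)."""

    def __init__(self, n_in: int, n_units: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.n_in, self.n_units = n_in, n_units
        self.return_sequences = return_sequences
        self.W = _glorot(rng, n_in, 4 * n_units)
        self.U = _glorot(rng, n_units, 4 * n_units)
        self.b = np.zeros(4 * n_units)
        self.b[n_units:2 * n_units] = 1.0
        self.activation = "lstm"

    def params(self):
        return [self.W, self.U, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        B, T, _ = X.shape
        n = self.n_units
        H = np.zeros((B, T + 1, n))
        C = np.zeros((B, T + 1, n))
        gates = np.zeros((B, T, 4 * n))
        for t in range(T):
            z = X[:, t] @ self.W + H[:, t] @ self.U + self.b
            i = _sigmoid(z[:, :n])
            f = _sigmoid(z[:, n:2 * n])
            o = _sigmoid(z[:, 2 * n:3 * n])
            g = np.tanh(z[:, 3 * n:])
            C[:, t + 1] = f * C[:, t] + i * g
            H[:, t + 1] = o * np.tanh(C[:, t + 1])
            gates[:, t] = np.concatenate([i, f, o, g], axis=1)
        self._X, self._H, self._C, self._gates = X, H, C, gates
        return H[:, 1:] if self.return_sequences else H[:, -1]

    def backward(self, dY: np.ndarray):
        X, H, C, gates = self._X, self._H, self._C, self._gates
        B, T, _ = X.shape
        n = self.n_units
        dW = np.zeros_like(self.W)
        dU = np.zeros_like(self.U)
        db = np.zeros_like(self.b)
        dX = np.zeros_like(X)
        dh_carry = np.zeros((B, n))
        dc_carry = np.zeros((B, n))
        for t in range(T - 1, -1, -1):
            dh = dh_carry.copy()
            if self.return_sequences:
                dh += dY[:, t]
            elif t == T - 1:
                dh += dY
            i = gates[:, t, :n]
            f = gates[:, t, n:2 * n]
            o = gates[:, t, 2 * n:3 * n]
            g = gates[:, t, 3 * n:]
            c_new = C[:, t + 1]
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dc = dh * o * (1.0 - tanh_c ** 2) + dc_carry
            di = dc * g
            df = dc * C[:, t]
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                do * o * (1 - o), dg * (1 - g * g)], axis=1)
            dW += X[:, t].T @ dz
            dU += H[:, t].T @ dz
            db += dz.sum(axis=0)
            dh_carry = dz @ self.U.T
            dc_carry = dc * f
            dX[:, t] = dz @ self.W.T
        self._grads = [dW, dU, db]
        return dX


class DenseLayer:
    """Fully connected layer with relu or linear activation."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str = "relu"):
        self.W = _glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.activation = activation

    def params(self):
        return [self.W, self.b]

    def forward(self, X: np.ndarray) -> np.ndarray:
        Z = X @ self.W + self.b
        if self.activation == "relu":
            Z = np.maximum(Z, 0.0)
        self._X, self._Z = X, Z
        return Z

    def backward(self, dY: np.ndarray):
        if self.activation == "relu":
            dY = dY * (self._Z > 0)
        self._grads = [self._X.T @ dY, dY.sum(axis=0)]
        return dY @ self.W.T


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


class SequenceRegressor:
    """Stacked recurrent network with a dense head and scalar output."""

    def __init__(self, layers: list):
        self.layers = layers

    @classmethod
    def build(cls, kind: str, n_features: int, rng: np.random.Generator,
              units: tuple[int, int, int] | None = None) -> "SequenceRegressor":
        if kind == "lstm":
            u = units or (64, 32, 64)
            layers = [LSTMLayer(n_features, u[0], rng, return_sequences=True),
                      LSTMLayer(u[0], u[1], rng, return_sequences=False),
                      DenseLayer(u[1], u[2], rng, "relu"),
                      DenseLayer(u[2], 1, rng, "linear")]
        elif kind == "rnn":
            u = units or (128, 64, 128)
            layers = [SimpleRNNLayer(n_features, u[0], rng, "sigmoid",
                                     return_sequences=True),
                      SimpleRNNLayer(u[0], u[1], rng, "sigmoid",
                                     return_sequences=False),
                      DenseLayer(u[1], u[2], rng, "relu"),
                      DenseLayer(u[2], 1, rng, "linear")]
        else:
            raise ValueError(f"unknown network kind {kind!r}")
        return cls(layers)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, X: np.ndarray) -> np.ndarray:
        out = X
        for layer in self.layers:
            out = layer.forward(out)
        return out[:, 0]

    def backward(self, dloss: np.ndarray) -> list[np.ndarray]:
        grad = dloss[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return [g for layer in self.layers for g in layer._grads]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)

    def mse(self, X: np.ndarray, y: np.ndarray, batch: int = 512) -> float:
        se = 0.0
        for k in range(0, len(y), batch):
            pred = self.forward(X[k:k + batch])
            se += float(((pred - y[k:k + batch]) ** 2).sum())
        return se / len(y)

    def fit(self, X: np.ndarray, y: np.ndarray, *, epochs: int = 30,
            batch_size: int = 64, lr: float = 1e-3, seed: int = 0,
            validation_split: float = 0.1, patience: int = 5,
            verbose: bool = False) -> dict:
        """Minibatch Adam on MSE with early stopping on a held-out tail.

        Returns a history dict with per-epoch train/validation loss."""
        rng = np.random.default_rng(seed)
        n = len(y)
        n_val = int(round(n * validation_split)) if validation_split > 0 else 0
        if n_val > 0:
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            Xv, yv = X[val_idx], y[val_idx]
            Xt, yt = X[tr_idx], y[tr_idx]
        else:
            Xt, yt = X, y
            Xv = yv = None
        opt = Adam(self.params(), lr=lr)
        history = {"loss": [], "val_loss": []}
        best_val = np.inf
        best_state = None
        stall = 0
        for epoch in range(epochs):
            order = rng.permutation(len(yt))
            ep_loss = 0.0
            for k in range(0, len(yt), batch_size):
                idx = order[k:k + batch_size]
                xb, yb = Xt[idx], yt[idx]
                pred = self.forward(xb)
                err = pred - yb
                loss = float((err ** 2).mean())
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, batch {k // batch_size}")
                grads = self.backward(2.0 * err / len(yb))
                opt.step(grads)
                ep_loss += loss * len(yb)
            history["loss"].append(ep_loss / len(yt))
            if Xv is not None:
                vl = self.mse(Xv, yv)
                history["val_loss"].append(vl)
                if vl < best_val - 1e-12:
                    best_val = vl
                    best_state = [p.copy() for p in self.params()]
                    stall = 0
                else:
                    stall += 1
                    if stall >= patience:
                        break
            if verbose:
                print(f"epoch {epoch}: loss={history['loss'][-1]:.5f}")
        if best_state is not None:
            for p, s in zip(self.params(), best_state):
                p[...] = s
        return history
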