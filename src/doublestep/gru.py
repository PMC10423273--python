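"""A compact gated-recurrent-unit (GRU) network in numpy.

Implements the small sequence models used for goal classification and
future-trajectory regression: a single GRU layer read out at the last time
step by a dense head (softmax + categorical cross-entropy for
classification, linear + mean-squared error for regression), trained with
Adam and early stopping on a held-out validation split.

The networks are deliberately tiny (inputs are 8-step windows of 6 kinematic
features), so plain vectorised numpy is fast enough and keeps training fully
deterministic under a seed.

GRU equations (per time step t, batch row-major)::

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)        update gate
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)        reset gate
    c_t = tanh(x_t Wc + (r_t * h_{t-1}) Uc + bc)   candidate state
    h_t = z_t * h_{t-1} + (1 - z_t) * c_t
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["GRUNet", "TrainConfig", "train_network"]


@dataclass
class TrainConfig:
    """Optimisation settings (Adam, minibatch, early stopping)."""

    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 10_000
    patience: int = 500
    validation_fraction: float = 0.2
    hidden_units: int = 100
    seed: int = 0

    def reduced(self, max_epochs: int = 120, patience: int = 15) -> "TrainConfig":
        """Copy with a tighter epoch budget for desk-scale runs."""
        out = TrainConfig(**self.__dict__)
        out.max_epochs = max_epochs
        out.patience = patience
        return out


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _softmax(x: np.ndarray) -> np.ndarray:
    x = x - x.max(axis=1, keepdims=True)
    e = np.exp(x)
    return e / e.sum(axis=1, keepdims=True)


class GRUNet:
    """Single-layer GRU + dense head, with manual backprop through time.

    Parameters
    ----------
    n_features : input features per time step (K)
    n_hidden : GRU units
    n_out : output units (classes for task="classify", targets for "regress")
    task : "classify" (softmax/cross-entropy) or "regress" (linear/MSE)
    seed : parameter-initialisation seed
    """

    def __init__(self, n_features: int, n_hidden: int, n_out: int,
                 task: str = "classify", seed: int = 0, dtype=np.float64):
        if task not in ("classify", "regress"):
            raise ValueError("task must be 'classify' or 'regress'")
        self.task = task
        self.nf, self.nh, self.no = n_features, n_hidden, n_out
        rng = np.random.default_rng(seed)
        glorot = lambda fan_in, fan_out: rng.uniform(
            -np.sqrt(6.0 / (fan_in + fan_out)), np.sqrt(6.0 / (fan_in + fan_out)),
            size=(fan_in, fan_out))
        def ortho(n):
            q, r = np.linalg.qr(rng.normal(size=(n, n)))
            return q * np.sign(np.diag(r))
        self.params = {
            "Wx": glorot(n_features, 3 * n_hidden).astype(dtype),  # [z | r | c] blocks
            "Uzr": np.concatenate([ortho(n_hidden), ortho(n_hidden)], axis=1).astype(dtype),
            "Uc": ortho(n_hidden).astype(dtype),
            "b": np.zeros(3 * n_hidden, dtype=dtype),
            "Wo": glorot(n_hidden, n_out).astype(dtype),
            "bo": np.zeros(n_out, dtype=dtype),
        }

    # -- forward -----------------------------------------------------------
    def _recur(self, X: np.ndarray, keep: bool = False):
        """Run the GRU over X (N, T, F); returns last hidden state and, if
        ``keep``, the per-step activations needed for backprop."""
        N, T, _ = X.shape
        p = self.params
        nh = self.nh
        h = np.zeros((N, nh), dtype=p["Wx"].dtype)
        xw = X.reshape(N * T, self.nf) @ p["Wx"]
        xw = xw.reshape(N, T, 3 * nh) + p["b"]
        cache = []
        for t in range(T):
            pre = xw[:, t, :]
            zr = _sigmoid(pre[:, : 2 * nh] + h @ p["Uzr"])
            z, r = zr[:, :nh], zr[:, nh:]
            rh = r * h
            c = np.tanh(pre[:, 2 * nh:] + rh @ p["Uc"])
            h_new = z * h + (1.0 - z) * c
            if keep:
                cache.append((h, z, r, rh, c))
            h = h_new
        return h, cache

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Network output: class probabilities (classify) or predictions."""
        h, _ = self._recur(np.asarray(X))
        out = h @ self.params["Wo"] + self.params["bo"]
        return _softmax(out) if self.task == "classify" else out

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class labels (classify) or predicted values (regress)."""
        out = self.forward(X)
        return out.argmax(axis=1) if self.task == "classify" else out

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy (classify, integer labels) or MSE (regress)."""
        out = self.forward(X)
        if self.task == "classify":
            p = np.clip(out[np.arange(len(y)), y], 1e-12, None)
            return float(-np.mean(np.log(p)))
        return float(np.mean((out - y) ** 2))

    # -- backward ----------------------------------------------------------
    def gradients(self, X: np.ndarray, y: np.ndarray) -> tuple[float, dict]:
        """Loss and parameter gradients for one minibatch (BPTT)."""
        X = np.asarray(X)
        N, T, _ = X.shape
        p = self.params
        nh = self.nh
        h_last, cache = self._recur(X, keep=True)
        out = h_last @ p["Wo"] + p["bo"]
        if self.task == "classify":
            prob = _softmax(out)
            loss = float(-np.mean(np.log(np.clip(prob[np.arange(N), y], 1e-12, None))))
            dout = prob.copy()
            dout[np.arange(N), y] -= 1.0
            dout /= N
        else:
            diff = out - y
            loss = float(np.mean(diff ** 2))
            dout = 2.0 * diff / diff.size

        g = {k: np.zeros_like(v) for k, v in p.items()}
        g["Wo"] = h_last.T @ dout
        g["bo"] = dout.sum(axis=0)
        dh = dout @ p["Wo"].T

        dpre = np.empty((N, T, 3 * nh), dtype=X.dtype)  # grads wrt xw + b rows
        Uzr_T = p["Uzr"].T
        Uc_T = p["Uc"].T
        for t in range(T - 1, -1, -1):
            h_prev, z, r, rh, c = cache[t]
            dz = dh * (h_prev - c) * z * (1.0 - z)
            dc = dh * (1.0 - z) * (1.0 - c * c)
            drh = dc @ Uc_T
            dr = drh * h_prev * r * (1.0 - r)
            dpre[:, t, :nh] = dz
            dpre[:, t, nh: 2 * nh] = dr
            dpre[:, t, 2 * nh:] = dc
            g["Uc"] += rh.T @ dc
            dh = dh * z + drh * r + np.concatenate([dz, dr], axis=1) @ Uzr_T
        # accumulate recurrent zr grads in one pass
        for t in range(T):
            h_prev = cache[t][0]
            g["Uzr"] += h_prev.T @ dpre[:, t, : 2 * nh]
        flat = dpre.reshape(N * T, 3 * nh)
        g["Wx"] = X.reshape(N * T, self.nf).T @ flat
        g["b"] = flat.sum(axis=0)
        return loss, g

    def get_weights(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, w: dict) -> None:
        for k in self.params:
            self.params[k] = w[k].copy()


class _Adam:
    def __init__(self, params: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, gk in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * gk
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * gk * gk
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


def _validation_split(n: int, y: Optional[np.ndarray], frac: float,
                      rng: np.random.Generator, stratify: bool) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n)
    if stratify and y is not None:
        val = []
        for cls in np.unique(y):
            members = rng.permutation(idx[y == cls])
            k = max(1, int(round(frac * len(members))))
            val.extend(members[:k])
        val = np.array(sorted(val))
    else:
        perm = rng.permutation(idx)
        k = max(1, int(round(frac * n)))
        val = np.sort(perm[:k])
    train = np.setdiff1d(idx, val)
    return train, val


def train_network(
    X: np.ndarray,
    y: np.ndarray,
    task: str,
    n_out: int,
    config: TrainConfig,
) -> GRUNet:
    """Train a GRU network on chunks ``X`` (N, T, K).

    Classification: ``y`` integer labels in [0, n_out); regression: ``y``
    of shape (N, n_out).  A seeded validation split (stratified for
    classification) drives early stopping: training halts when the
    validation loss has not improved for ``config.patience`` epochs, and the
    best-validation weights are restored.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if task == "classify" and len(np.unique(y)) < 2:
        raise ValueError("classification needs at least two classes")
    rng = np.random.default_rng(config.seed)
    net = GRUNet(X.shape[2], config.hidden_units, n_out, task=task,
                 seed=int(rng.integers(2**31 - 1)))
    tr_idx, val_idx = _validation_split(
        len(X), y if task == "classify" else None,
        config.validation_fraction, rng, stratify=(task == "classify"))
    Xtr, ytr = X[tr_idx], y[tr_idx]
    Xval, yval = X[val_idx], y[val_idx]

    opt = _Adam(net.params, config.learning_rate)
    best_loss = np.inf
    best_w = net.get_weights()
    stall = 0
    for _ in range(config.max_epochs):
        order = rng.permutation(len(Xtr))
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            _, grads = net.gradients(Xtr[batch], ytr[batch])
            opt.step(net.params, grads)
        vloss = net.loss(Xval, yval)
        if vloss < best_loss - 1e-9:
            best_loss = vloss
            best_w = net.get_weights()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    net.set_weights(best_w)
    net.best_val_loss_ = best_loss
    return net
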