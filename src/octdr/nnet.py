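"""Backpropagation neural network (BNN): a single-hidden-layer feed-forward
net with tanh hidden units and softmax output, trained by gradient descent
with momentum on the cross-entropy loss.

This is the fusion unit used twice in the pipeline: per-layer (4 marker
probabilities -> 49 hidden -> 2) and globally (12 layer probabilities ->
30 hidden -> 2).  Weights, training and prediction are plain numpy so the
analytic gradients are inspectable (and finite-difference checkable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _one_hot(y: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((y.size, n_classes))
    out[np.arange(y.size), y] = 1.0
    return out


@dataclass
class BNNParams:
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 2000
    patience: int = 100
    plateau_tol: float = 1e-6
    weight_scale: float = 0.5


class BNN:
    """One-hidden-layer backpropagation network, deterministic per seed."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int = 2,
                 params: BNNParams | None = None, seed: int = 0) -> None:
        if n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.params = params or BNNParams()
        rng = np.random.default_rng(seed)
        s = self.params.weight_scale
        self.W1 = rng.uniform(-s, s, (n_in, n_hidden)) / np.sqrt(n_in)
        self.b1 = np.zeros(n_hidden)
        self.W2 = rng.uniform(-s, s, (n_hidden, n_out)) / np.sqrt(n_hidden)
        self.b2 = np.zeros(n_out)
        self.loss_history: list[float] = []

    # ---- forward / loss / gradients -------------------------------------

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.tanh(X @ self.W1 + self.b1)
        p = _softmax(h @ self.W2 + self.b2)
        return h, p

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} inputs, got {X.shape[1]}")
        return self.forward(X)[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def loss(self, X: np.ndarray, T: np.ndarray) -> float:
        _, p = self.forward(X)
        return float(-np.mean(np.sum(T * np.log(p + 1e-12), axis=1)))

    def gradients(self, X: np.ndarray, T: np.ndarray):
        """Analytic gradients of the mean cross-entropy loss."""
        n = X.shape[0]
        h, p = self.forward(X)
        dz2 = (p - T) / n
        dW2 = h.T @ dz2
        db2 = dz2.sum(axis=0)
        dh = dz2 @ self.W2.T
        dz1 = dh * (1.0 - h ** 2)
        dW1 = X.T @ dz1
        db1 = dz1.sum(axis=0)
        return dW1, db1, dW2, db2

    # ---- training -------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BNN":
        """Full-batch gradient descent with momentum until the epoch cap or
        a training-loss plateau (``patience`` epochs without improvement
        beyond ``plateau_tol``)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite training inputs")
        T = _one_hot(y, self.n_out)
        p = self.params
        vel = [np.zeros_like(w) for w in (self.W1, self.b1, self.W2, self.b2)]
        best = np.inf
        stall = 0
        self.loss_history = []
        for _ in range(p.max_epochs):
            grads = self.gradients(X, T)
            weights = (self.W1, self.b1, self.W2, self.b2)
            for v, w, g in zip(vel, weights, grads):
                v *= p.momentum
                v -= p.learning_rate * g
                w += v
            cur = self.loss(X, T)
            if not np.isfinite(cur):
                raise FloatingPointError(
                    f"NaN/inf training loss at epoch {len(self.loss_history)}; "
                    f"lr={p.learning_rate}")
            self.loss_history.append(cur)
            if cur < best - p.plateau_tol:
                best = cur
                stall = 0
            else:
                stall += 1
                if stall >= p.patience:
                    break
        return self

    # ---- persistence ----------------------------------------------------

    def state_dict(self) -> dict:
        return {"W1": self.W1, "b1": self.b1, "W2": self.W2, "b2": self.b2,
                "n_in": self.n_in, "n_hidden": self.n_hidden,
                "n_out": self.n_out}

    @classmethod
    def from_state(cls, state: dict) -> "BNN":
        net = cls(int(state["n_in"]), int(state["n_hidden"]),
                  int(state["n_out"]))
        net.W1 = np.asarray(state["W1"]); net.b1 = np.asarray(state["b1"])
        net.W2 = np.asarray(state["W2"]); net.b2 = np.asarray(state["b2"])
        return net
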