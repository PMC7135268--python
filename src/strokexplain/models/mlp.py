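"""One-hidden-layer perceptron with a two-way softmax head.

Architecture: input -> rectified hidden layer (M units) -> 2-class softmax.
Training minimizes binary cross-entropy plus an L1 penalty on the weights
with plain minibatch SGD. Regularization follows the classic dropout
scheme: hidden units are dropped with probability DR during training
(without rescaling), and at inference every hidden output is weighted by
(1 - DR) to yield its expected value.

The fitted object exposes its weights and per-layer activations so the
relevance-propagation module can walk the network backwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPHyperparams", "MLPParams", "fit_mlp", "loss_and_grads"]


@dataclass(frozen=True)
class MLPHyperparams:
    hidden_units: int = 10
    learning_rate: float = 0.01
    batch_size: int = 32
    dropout_rate: float = 0.1
    l1: float = 0.0001
    max_epochs: int = 300
    patience: int = 20
    tol: float = 1e-6


@dataclass
class MLPParams:
    W1: np.ndarray  # (n_features, M)
    b1: np.ndarray  # (M,)
    W2: np.ndarray  # (M, 2)
    b2: np.ndarray  # (2,)
    dropout_rate: float
    hyperparams: MLPHyperparams | None = None
    loss_history: list = field(default_factory=list)

    @property
    def n_features(self) -> int:
        return self.W1.shape[0]

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """Rectified hidden outputs at inference, (1-DR)-weighted."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features")
        a = np.maximum(0.0, X @ self.W1 + self.b1)
        return a * (1.0 - self.dropout_rate)

    def logits(self, X: np.ndarray) -> np.ndarray:
        return self.hidden_activations(X) @ self.W2 + self.b2

    def predict_proba_2(self, X: np.ndarray) -> np.ndarray:
        z = self.logits(X)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of the bad-outcome class (class 1)."""
        return self.predict_proba_2(X)[:, 1]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def loss_and_grads(W1, b1, W2, b2, X, y, l1=0.0, drop_mask=None):
    """Cross-entropy + L1 loss and its analytic gradients for one batch.

    ``drop_mask`` (n, M) of 0/1 applies training-time dropout to the hidden
    layer. Exposed at module level so the gradients can be checked against
    finite differences.
    """
    n = len(y)
    a1 = np.maximum(0.0, X @ W1 + b1)
    if drop_mask is not None:
        a1 = a1 * drop_mask
    z2 = a1 @ W2 + b2
    p = _softmax(z2)
    eps = 1e-12
    ce = -np.log(p[np.arange(n), y] + eps).mean()
    loss = ce + l1 * (np.abs(W1).sum() + np.abs(W2).sum())

    dz2 = p.copy()
    dz2[np.arange(n), y] -= 1.0
    dz2 /= n
    gW2 = a1.T @ dz2 + l1 * np.sign(W2)
    gb2 = dz2.sum(axis=0)
    da1 = dz2 @ W2.T
    if drop_mask is not None:
        da1 = da1 * drop_mask
    da1 = da1 * (a1 > 0)
    gW1 = X.T @ da1 + l1 * np.sign(W1)
    gb1 = da1.sum(axis=0)
    return loss, (gW1, gb1, gW2, gb2)


def fit_mlp(X, y, hp: MLPHyperparams = MLPHyperparams(), seed: int = 0) -> MLPParams:
    """Seeded minibatch SGD training with early stop on stalled loss.

    Stops when the epoch-mean training loss has not improved by ``tol``
    for ``patience`` consecutive epochs, or at ``max_epochs``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("X must be complete (impute first)")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    n, d = X.shape
    M = hp.hidden_units
    rng = np.random.default_rng(seed)
    # He initialization for the rectified layer, small normal for the head
    W1 = rng.normal(0.0, np.sqrt(2.0 / d), size=(d, M))
    b1 = np.zeros(M)
    W2 = rng.normal(0.0, np.sqrt(1.0 / M), size=(M, 2))
    b2 = np.zeros(2)

    best_loss, stall = np.inf, 0
    history = []
    for _ in range(hp.max_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, hp.batch_size):
            idx = order[start : start + hp.batch_size]
            mask = None
            if hp.dropout_rate > 0:
                mask = (rng.random((len(idx), M)) >= hp.dropout_rate).astype(float)
            loss, (gW1, gb1, gW2, gb2) = loss_and_grads(
                W1, b1, W2, b2, X[idx], y[idx], hp.l1, mask
            )
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            W1 -= hp.learning_rate * gW1
            b1 -= hp.learning_rate * gb1
            W2 -= hp.learning_rate * gW2
            b2 -= hp.learning_rate * gb2
            epoch_loss += loss
            n_batches += 1
        epoch_loss /= n_batches
        history.append(epoch_loss)
        if epoch_loss < best_loss - hp.tol:
            best_loss, stall = epoch_loss, 0
        else:
            stall += 1
            if stall >= hp.patience:
                break

    return MLPParams(
        W1=W1, b1=b1, W2=W2, b2=b2,
        dropout_rate=hp.dropout_rate, hyperparams=hp, loss_history=history,
    )
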