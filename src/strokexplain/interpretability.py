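"""Model-tailored feature-importance methods and their common normalization.

Three routes produce a raw per-feature importance vector:

* linear models — the fitted coefficient vector (meaningful because the
  features are standardized and nearly collinearity-free);
* tree ensembles — exact Shapley values of the prediction function,
  enumerated over all feature subsets with an interventional value
  function, averaged (signed) over observations;
* the MLP — layer-wise relevance propagation with the z+ (alpha=1, beta=0)
  rule, a deep Taylor decomposition, aggregated over observations with
  confidence-of-prediction weights.

Raw vectors from the three routes live on different scales; the common
currency is the normalization step: per shuffle, absolute values scaled to
unit sum, then mean and standard deviation per feature across shuffles.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .models.mlp import MLPParams

__all__ = [
    "ImportanceVector",
    "RelevanceMap",
    "linear_importance",
    "exact_shapley",
    "shapley_matrix",
    "aggregate_shap",
    "lrp_deep_taylor",
    "confidence_weighted_rating",
    "normalize_importance",
]

MAX_EXACT_FEATURES = 15


@dataclass
class ImportanceVector:
    scores: np.ndarray
    normalized: bool
    provenance: str  # e.g. "glm/coefficients", "gbdt/shap", "mlp/deep_taylor"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.normalized:
            if self.scores.min() < -1e-9 or self.scores.max() > 1 + 1e-9:
                raise ValueError("normalized scores must lie in [0,1]")
            if abs(self.scores.sum() - 1.0) > 1e-9:
                raise ValueError("normalized scores must sum to 1")


@dataclass
class RelevanceMap:
    """Per-layer relevances for one observation (output -> hidden -> input)."""

    output_relevance: float
    hidden_relevance: np.ndarray
    input_relevance: np.ndarray


def linear_importance(params) -> ImportanceVector:
    """Raw importance of a fitted linear model: its coefficient vector."""
    coef = getattr(params, "coefficients", None)
    if coef is None:
        raise ValueError("model has no fitted coefficients")
    return ImportanceVector(
        scores=np.asarray(coef, dtype=float).copy(),
        normalized=False,
        provenance=f"{getattr(params, 'kind', 'linear')}/coefficients",
    )


def exact_shapley(predict, x, background, features=None) -> np.ndarray:
    """Exact Shapley values by full subset enumeration.

    ``predict`` maps an (n, p) matrix to a score per row (typically the
    bad-outcome probability). For each feature i, phi_i is the sum over all
    subsets S of the remaining features of
    ``|S|! (|F|-|S|-1)! / |F|! * [v(S u {i}) - v(S)]`` with the
    interventional value function above. Cost is 2^|F| background batches,
    so |F| is capped at 15.
    """
    x = np.asarray(x, dtype=float).ravel()
    bg = np.asarray(background, dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ValueError("background must be a non-empty matrix")
    if bg.shape[1] != len(x):
        raise ValueError("background width must match the observation")
    all_features = list(range(len(x))) if features is None else list(features)
    F = len(all_features)
    if F > MAX_EXACT_FEATURES:
        raise ValueError(
            f"{F} features exceeds the exact-enumeration cap of "
            f"{MAX_EXACT_FEATURES}; use a sampling approximation instead"
        )

    # value for every subset of the active features, via one batched predict
    bg_full = bg
    n_sub = 1 << F
    n_bg = len(bg_full)
    stacked = np.tile(bg_full, (n_sub, 1))
    for mask in range(1, n_sub):
        block = stacked[mask * n_bg : (mask + 1) * n_bg]
        for pos, j in enumerate(all_features):
            if mask >> pos & 1:
                block[:, j] = x[j]
    preds = np.asarray(predict(stacked), dtype=float)
    v = preds.reshape(n_sub, n_bg).mean(axis=1)

    fact = [math.factorial(i) for i in range(F + 1)]
    weights = [fact[s] * fact[F - s - 1] / fact[F] for s in range(F)]
    phi = np.zeros(len(x))
    for pos, j in enumerate(all_features):
        others = [p for p in range(F) if p != pos]
        for r in range(F):
            w = weights[r]
            for combo in itertools.combinations(others, r):
                mask = 0
                for p in combo:
                    mask |= 1 << p
                phi[j] += w * (v[mask | (1 << pos)] - v[mask])
    return phi


def shapley_matrix(predict, X, background) -> np.ndarray:
    """Exact Shapley values for each row of X; (n_obs, n_features)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.vstack([exact_shapley(predict, row, background) for row in X])


def aggregate_shap(per_observation_phis) -> ImportanceVector:
    """Mean signed Shapley value per feature across observations."""
    phis = np.atleast_2d(np.asarray(per_observation_phis, dtype=float))
    if phis.size == 0:
        raise ValueError("no Shapley values to aggregate")
    return ImportanceVector(
        scores=phis.mean(axis=0), normalized=False, provenance="gbdt/shap"
    )


def lrp_deep_taylor(mlp: MLPParams, x, seed_output: str = "bad") -> RelevanceMap:
    """z+ -rule relevance propagation through the one-hidden-layer MLP.

    Relevance is seeded at one output neuron with that class's predicted
    probability and redistributed backwards through positive weights only,
    each neuron j receiving ``a_j w+_jk / sum_j a_j w+_jk`` of neuron k's
    relevance (bias terms excluded, so each step conserves the total when
    activations are non-negative). Neurons with a zero denominator
    propagate zero relevance.

    ``seed_output="bad"`` (default) always decomposes the bad-outcome
    probability, so relevances refer to the same explanandum for every
    observation — the quantity the other models' importances also
    decompose; ``"predicted"`` seeds at the argmax class instead.
    """
    if seed_output not in ("bad", "predicted"):
        raise ValueError("seed_output must be 'bad' or 'predicted'")
    x = np.asarray(x, dtype=float).ravel()
    a_hidden = mlp.hidden_activations(x)[0]
    if not np.isfinite(a_hidden).all():
        raise ValueError("non-finite activations in the forward pass")
    probs = mlp.predict_proba_2(x)[0]
    if not np.isfinite(probs).all():
        raise ValueError("non-finite activations in the forward pass")
    k_star = 1 if seed_output == "bad" else int(np.argmax(probs))
    r_out = float(probs[k_star])

    def propagate(activations, weights, upper_relevance):
        w_pos = np.maximum(0.0, weights)  # (lower, upper)
        z = activations @ w_pos           # denominator per upper neuron
        upper = np.asarray(upper_relevance, dtype=float)
        share = np.where(z > 0, upper / np.where(z > 0, z, 1.0), 0.0)
        return activations * (w_pos @ share)

    r_hidden = propagate(a_hidden, mlp.W2, np.eye(2)[k_star] * r_out)
    r_input = propagate(x, mlp.W1, r_hidden)
    return RelevanceMap(
        output_relevance=r_out,
        hidden_relevance=r_hidden,
        input_relevance=r_input,
    )


def confidence_weighted_rating(relevance_per_obs, predicted_prob, labels) -> ImportanceVector:
    """R(f) = (1/N) sum_i theta_i r_i(f), theta_i = y_i P_i + (1-y_i)(1-P_i).

    theta is the probability the model assigned to the observation's true
    class, so confidently correct predictions dominate the rating.
    """
    R = np.atleast_2d(np.asarray(relevance_per_obs, dtype=float))
    P = np.asarray(predicted_prob, dtype=float)
    y = np.asarray(labels)
    if len(R) != len(P) or len(P) != len(y):
        raise ValueError("relevances, probabilities and labels must align")
    if P.min() < 0 or P.max() > 1:
        raise ValueError("probabilities must lie in [0,1]")
    theta = y * P + (1 - y) * (1 - P)
    return ImportanceVector(
        scores=(theta[:, None] * R).mean(axis=0),
        normalized=False,
        provenance="mlp/deep_taylor",
    )


def normalize_importance(raw_vectors) -> dict:
    """Unit-sum normalization per shuffle, then mean +/- SD per feature.

    Each raw vector's absolute values are scaled to sum to one (so every
    entry lies in [0,1]); all-zero vectors are excluded with a warning.
    Returns normalized per-shuffle vectors and their per-feature mean/SD.
    """
    normalized = []
    for i, vec in enumerate(raw_vectors):
        scores = vec.scores if isinstance(vec, ImportanceVector) else np.asarray(vec, dtype=float)
        total = np.abs(scores).sum()
        if total == 0:
            warnings.warn(f"all-zero importance vector at position {i}; excluded")
            continue
        normalized.append(np.abs(scores) / total)
    if not normalized:
        raise ValueError("no nonzero importance vectors to normalize")
    mat = np.vstack(normalized)
    return {
        "normalized": mat,
        "mean": mat.mean(axis=0),
        "sd": mat.std(axis=0),
        "n_used": len(normalized),
    }
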