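"""Logistic-regression family: unregularized GLM, Lasso (L1) and elastic net.

All three maximize the binomial log-likelihood; Lasso adds an L1 penalty
parameterized by the inverse strength C, and the elastic net adds a mixed
L1/L2 penalty parameterized by a total strength ``alpha`` and an
``l1_ratio`` mixing weight. Intercepts are never penalized. Fitting is
delegated to scikit-learn's solvers (lbfgs for the smooth problem, saga for
the L1 terms); feature importance downstream is simply the coefficient
vector, which is meaningful here because the features are standardized and
nearly collinearity-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

__all__ = ["LinearModelParams", "fit_glm", "fit_lasso", "fit_elastic_net"]


@dataclass
class LinearModelParams:
    coefficients: np.ndarray
    intercept: float
    kind: str  # "glm" | "lasso" | "elastic_net"
    hyperparams: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def n_features(self) -> int:
        return len(self.coefficients)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Probability of a bad outcome via the logistic link."""
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))


def _check_inputs(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ValueError("X must be complete (impute first)")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    return X, y


def _wrap(clf, kind, hyperparams) -> LinearModelParams:
    converged = int(getattr(clf, "n_iter_", [0])[0]) < clf.max_iter
    return LinearModelParams(
        coefficients=clf.coef_.ravel().copy(),
        intercept=float(clf.intercept_[0]),
        kind=kind,
        hyperparams=hyperparams,
        converged=converged,
    )


def fit_glm(X, y) -> LinearModelParams:
    """Maximum-likelihood logistic regression, no penalty.

    Perfect separation cannot diverge: the solver stops at its iteration
    cap and the result is flagged via ``converged``.
    """
    X, y = _check_inputs(X, y)
    clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-8, max_iter=10_000)
    clf.fit(X, y)
    return _wrap(clf, "glm", {})


def fit_lasso(X, y, C: float) -> LinearModelParams:
    """L1-penalized logistic regression; C is the inverse penalty strength."""
    if C <= 0:
        raise ValueError("C must be positive")
    X, y = _check_inputs(X, y)
    clf = LogisticRegression(
        l1_ratio=1.0, C=C, solver="saga", tol=1e-8, max_iter=10_000, random_state=0
    )
    clf.fit(X, y)
    return _wrap(clf, "lasso", {"C": C})


def fit_elastic_net(X, y, alpha: float, l1_ratio: float) -> LinearModelParams:
    """Mixed L1/L2-penalized logistic regression.

    The penalty added to the summed negative log-likelihood is
    ``alpha * (l1_ratio * ||b||_1 + (1 - l1_ratio)/2 * ||b||_2^2)``;
    ``l1_ratio = 1`` therefore coincides with Lasso at ``C = 1/alpha``.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    if not 0.0 <= l1_ratio <= 1.0:
        raise ValueError("l1_ratio must be in [0, 1]")
    X, y = _check_inputs(X, y)
    if alpha == 0:
        params = fit_glm(X, y)
        return LinearModelParams(
            coefficients=params.coefficients,
            intercept=params.intercept,
            kind="elastic_net",
            hyperparams={"alpha": alpha, "l1_ratio": l1_ratio},
            converged=params.converged,
        )
    clf = LogisticRegression(
        C=1.0 / alpha,
        l1_ratio=l1_ratio,
        solver="saga",
        tol=1e-8,
        max_iter=10_000,
        random_state=0,
    )
    clf.fit(X, y)
    return _wrap(clf, "elastic_net", {"alpha": alpha, "l1_ratio": l1_ratio})
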