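"""Shared test helpers: hand-built tree ensembles and an independent
permutation-sampling Shapley estimator used as an oracle."""

from __future__ import annotations

import numpy as np

from strokexplain.models.gbdt import GBDTParams, Tree, TreeEnsemble


def make_tree(feature, threshold, left_value, right_value) -> Tree:
    """Single-split (depth-1) tree: x[feature] <= threshold -> left_value."""
    return Tree(
        feature=np.array([feature, -1, -1]),
        threshold=np.array([threshold, 0.0, 0.0]),
        left=np.array([1, -1, -1]),
        right=np.array([2, -1, -1]),
        value=np.array([0.0, left_value, right_value]),
    )


def random_ensemble(
    rng: np.random.Generator,
    n_features: int = 7,
    n_trees: int = 25,
    feature_pool=None,
    scale: float = 0.3,
) -> TreeEnsemble:
    """Random depth-1 trees on features drawn from ``feature_pool``."""
    pool = list(range(n_features)) if feature_pool is None else list(feature_pool)
    trees = [
        make_tree(
            int(rng.choice(pool)),
            float(rng.normal()),
            float(rng.normal(scale=scale)),
            float(rng.normal(scale=scale)),
        )
        for _ in range(n_trees)
    ]
    return TreeEnsemble(
        trees=trees,
        base_score=float(rng.normal(scale=0.2)),
        params=GBDTParams(),
        n_features=n_features,
    )


def permutation_shapley(predict, x, background, n_perm, rng):
    """Monte-Carlo Shapley estimate by averaging marginal contributions over
    random feature orderings; returns (phi_hat, standard_error_per_feature).

    Independent of the exact subset-enumeration implementation: it only
    shares the interventional value function definition.
    """
    x = np.asarray(x, dtype=float)
    bg = np.asarray(background, dtype=float)
    p = len(x)
    contribs = np.zeros((n_perm, p))
    for t in range(n_perm):
        order = rng.permutation(p)
        current = bg.copy()
        v_prev = float(np.mean(predict(current)))
        for j in order:
            current[:, j] = x[j]
            v_new = float(np.mean(predict(current)))
            contribs[t, j] = v_new - v_prev
            v_prev = v_new
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_perm)
    return phi, se
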