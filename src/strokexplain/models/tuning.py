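"""Model-family registry, hyperparameter grids, and 10-fold CV tuning.

The default grids reproduce the study protocol's search ranges: Lasso over
50 values of the inverse strength C; elastic net over a 20x11 l1-ratio x
alpha lattice; the tree booster over depth, learning rate, bagging
temperature, L2 leaf regularization and leaf-estimation iterations; the
MLP over hidden units, learning rate, batch size, dropout rate and L1
ratio. The unpenalized GLM has nothing to tune.

Grid search is exhaustive; each candidate is scored by its mean held-out
AUC over a seeded k-fold partition, with ties broken toward stronger
regularization and then grid order.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path

import numpy as np
import yaml

from ..evaluation import roc_auc
from .gbdt import GBDTParams, fit_gbdt
from .linear import fit_elastic_net, fit_glm, fit_lasso
from .mlp import MLPHyperparams, fit_mlp

__all__ = [
    "MODEL_FAMILIES",
    "default_grids",
    "load_grids",
    "expand_grid",
    "fit_model",
    "predict_proba",
    "cross_validate",
]

_LASSO_C = [
    0.10, 0.12, 0.15, 0.18, 0.21, 0.26, 0.31, 0.37, 0.45, 0.54, 0.66, 0.79,
    0.95, 1.15, 1.39, 1.68, 2.02, 2.44, 2.95, 3.56, 4.29, 5.18, 6.25, 7.54,
    9.10, 10.9, 13.3, 16.0, 19.3, 23.3, 28.1, 33.9, 40.9, 49.4, 59.6, 72.0,
    86.9, 105, 126, 153, 184, 222, 268, 324, 391, 471, 569, 687, 829, 1000,
]

MODEL_FAMILIES = ("glm", "lasso", "elastic_net", "gbdt", "mlp")


def default_grids() -> dict:
    """Per-family hyperparameter search ranges (study defaults)."""
    return {
        "glm": {},
        "lasso": {"C": list(_LASSO_C)},
        "elastic_net": {
            "l1_ratio": [round(0.05 * i, 2) for i in range(20)],
            "alpha": [0.00001, 0.00004, 0.00016, 0.0006, 0.0025,
                      0.01, 0.04, 0.16, 0.63, 2.5, 10],
        },
        "gbdt": {
            "depth": [2, 4],
            "learning_rate": [0.03, 0.1, 0.3],
            "bagging_temperature": [0.6, 0.8, 1.0],
            "l2_leaf_reg": [3, 10, 100, 500],
            "leaf_estimation_iterations": [1, 2],
        },
        "mlp": {
            "hidden_units": [5, 10, 15, 20],
            "learning_rate": [0.001, 0.01],
            "batch_size": [16, 32],
            "dropout_rate": [0.1, 0.2],
            "l1": [0.0001, 0.001],
        },
    }


def load_grids(path: str | Path) -> dict:
    """Read per-family grids from YAML, filling omitted families from defaults."""
    user = yaml.safe_load(Path(path).read_text()) or {}
    grids = default_grids()
    for family, grid in user.items():
        if family not in grids:
            raise ValueError(f"unknown model family {family!r}")
        grids[family] = {k: list(v) for k, v in (grid or {}).items()}
    return grids


def expand_grid(grid: dict) -> list[dict]:
    """All combinations of the per-parameter candidate lists, in grid order."""
    if not grid:
        return [{}]
    keys = list(grid)
    for k in keys:
        if not grid[k]:
            raise ValueError(f"empty candidate list for {k!r}")
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def fit_model(family: str, X, y, config: dict, seed: int = 0, **extra):
    """Fit one model of the given family with one hyperparameter config."""
    if family == "glm":
        return fit_glm(X, y)
    if family == "lasso":
        return fit_lasso(X, y, **config)
    if family == "elastic_net":
        return fit_elastic_net(X, y, **config)
    if family == "gbdt":
        return fit_gbdt(X, y, GBDTParams(**{**config, **extra}), seed=seed)
    if family == "mlp":
        return fit_mlp(X, y, MLPHyperparams(**{**config, **extra}), seed=seed)
    raise ValueError(f"unknown model family {family!r}")


def predict_proba(model, X) -> np.ndarray:
    """Bad-outcome probability from any fitted family."""
    return model.predict_proba(np.asarray(X, dtype=float))


def _regularization_key(family: str, config: dict) -> tuple:
    """Sort key; larger = stronger regularization (preferred on AUC ties)."""
    if family == "lasso":
        return (-config["C"],)
    if family == "elastic_net":
        return (config["alpha"], config["l1_ratio"])
    if family == "gbdt":
        return (config["l2_leaf_reg"], -config["depth"])
    if family == "mlp":
        return (config["l1"], config["dropout_rate"], -config["hidden_units"])
    return (0,)


def cross_validate(
    family: str,
    X,
    y,
    grid: dict,
    k: int = 10,
    seed: int = 0,
    **extra,
) -> dict:
    """Exhaustive seeded k-fold grid search maximizing mean validation AUC.

    Folds are contiguous chunks of one seeded permutation, shared by every
    candidate. Single-class validation folds are skipped with a warning;
    if every fold is degenerate the search fails.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    configs = expand_grid(grid)
    if len(configs) == 1:
        return configs[0]

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    best = None  # (mean_auc, reg_key, -grid_position, config)
    for pos, config in enumerate(configs):
        aucs = []
        for i in range(k):
            val = folds[i]
            train = np.concatenate([folds[j] for j in range(k) if j != i])
            if len(np.unique(y[val])) < 2 or len(np.unique(y[train])) < 2:
                warnings.warn(f"fold {i} has a single class; skipped")
                continue
            model = fit_model(family, X[train], y[train], config, seed=seed, **extra)
            aucs.append(roc_auc(predict_proba(model, X[val]), y[val]))
        if not aucs:
            raise ValueError("all CV folds degenerate (single-class)")
        key = (float(np.mean(aucs)), _regularization_key(family, config), -pos)
        if best is None or key > best[0]:
            best = (key, config)
    return best[1]
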