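"""Data-preparation stages of the outcome-prediction protocol.

Order of operations per shuffle: dichotomize the 90-day mRS, split 4:1 into
train/test, impute (train mean for continuous, train mode for binary) and
z-score with train statistics, then randomly down-sample the training
majority class to a uniform class distribution. A variance-inflation-factor
screen guards the cross-model importance comparison against
multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import BINARY_FEATURES, FEATURES

__all__ = [
    "PreprocessState",
    "SplitIndices",
    "dichotomize_mrs",
    "split_train_test",
    "fit_preprocess",
    "apply_preprocess",
    "subsample_balance",
    "compute_vif",
]


def dichotomize_mrs(mrs) -> np.ndarray:
    """Binary bad-outcome label: mRS 0-2 -> 0 (good), mRS 3-6 -> 1 (bad)."""
    arr = np.asarray(mrs)
    if arr.size and (not np.issubdtype(arr.dtype, np.integer)):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("mRS values must be integers")
        arr = arr.astype(int)
    if arr.size and (arr.min() < 0 or arr.max() > 6):
        bad = arr[(arr < 0) | (arr > 6)]
        raise ValueError(f"mRS values outside {{0..6}}: {bad[:5]}")
    return (arr >= 3).astype(int)


@dataclass(frozen=True)
class SplitIndices:
    train: np.ndarray
    test: np.ndarray
    seed: int


def split_train_test(n_rows: int, seed: int) -> SplitIndices:
    """Uniform random 4:1 train/test split; test size = round(n/5)."""
    if n_rows < 5:
        raise ValueError("need at least 5 rows for a 4:1 split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_test = int(np.round(n_rows / 5))
    return SplitIndices(train=np.sort(perm[n_test:]), test=np.sort(perm[:n_test]), seed=seed)


@dataclass(frozen=True)
class PreprocessState:
    """Train-derived imputation values and scaling statistics.

    Fit on the training partition only; applying it to any table never
    updates the statistics, so test rows cannot leak into them.
    """

    feature_order: tuple
    impute_values: np.ndarray  # train mean (continuous) or mode (binary)
    means: np.ndarray          # post-imputation train means
    sds: np.ndarray            # post-imputation train sds (population)

    def to_dict(self) -> dict:
        return {
            "feature_order": list(self.feature_order),
            "impute_values": self.impute_values.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
        }


def fit_preprocess(train_features: pd.DataFrame) -> PreprocessState:
    """Learn mean/mode imputation values and z-scoring statistics from train."""
    cols = tuple(train_features.columns)
    arr = train_features.to_numpy(dtype=float)
    impute = np.empty(len(cols))
    for j, name in enumerate(cols):
        observed = arr[~np.isnan(arr[:, j]), j]
        if observed.size == 0:
            raise ValueError(f"column {name!r} has no observed values")
        if name in BINARY_FEATURES:
            values, counts = np.unique(observed, return_counts=True)
            impute[j] = float(values[np.argmax(counts)])  # ties -> smallest value
        else:
            impute[j] = float(observed.mean())
    filled = arr.copy()
    nan_mask = np.isnan(filled)
    filled[nan_mask] = np.broadcast_to(impute, filled.shape)[nan_mask]
    means = filled.mean(axis=0)
    sds = filled.std(axis=0)
    zero = sds <= 0
    if zero.any():
        bad = [cols[j] for j in np.where(zero)[0]]
        raise ValueError(f"zero-variance training column(s): {bad}; scale undefined")
    return PreprocessState(feature_order=cols, impute_values=impute, means=means, sds=sds)


def apply_preprocess(state: PreprocessState, features: pd.DataFrame) -> np.ndarray:
    """Impute with train values, then z-score with train mean/sd."""
    if tuple(features.columns) != state.feature_order:
        raise ValueError("feature columns do not match the fitted state")
    X = features.to_numpy(dtype=float)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.broadcast_to(state.impute_values, X.shape)[nan_mask]
    return (X - state.means) / state.sds


def subsample_balance(labels, seed: int) -> np.ndarray:
    """Down-sample the majority class to the minority count, keeping all
    minority rows; returns sorted retained row indices."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    maj_idx = np.where(y == majority)[0]
    keep_maj = rng.choice(maj_idx, size=n_min, replace=False)
    keep = np.concatenate([np.where(y == minority)[0], keep_maj])
    return np.sort(keep)


def compute_vif(features) -> pd.Series:
    """Variance inflation factor per feature: 1/(1-R^2) from regressing each
    feature on the others with an intercept. Exact collinearity gives inf."""
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"x{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 features for VIF")
    if n <= p:
        raise ValueError("need more rows than features for VIF")
    if np.isnan(X).any():
        raise ValueError("VIF requires complete cases (no missing values)")
    vifs = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Z = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Z, yj, rcond=None)
        resid = yj - Z @ coef
        tss = np.sum((yj - yj.mean()) ** 2)
        if tss == 0:
            vifs[j] = np.inf
            continue
        r2 = 1.0 - resid @ resid / tss
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(vifs, index=names, name="vif")
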