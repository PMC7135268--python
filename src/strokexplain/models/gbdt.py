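"""Gradient-boosted decision trees with logistic loss, from scratch.

The ensemble predicts the bad-outcome probability as the sigmoid of a base
score plus the cumulative sum of learning-rate-scaled leaf scores over K
axis-aligned regression trees. Each boosting stage fits a tree to the
current negative gradients of the (optionally observation-weighted)
logistic loss using greedy variance-reducing splits; leaf values are
L2-regularized Newton steps (penalty ``l2_leaf_reg`` on the leaf weights),
optionally refined by further Newton iterations on the updated margins.
Stochasticity enters through a bagging-temperature scheme: per-tree
observation weights ``u = e^t`` with ``e ~ Exp(1)``, normalized to mean 1,
so ``t = 0`` recovers deterministic boosting and larger ``t`` approaches a
Bayesian bootstrap.

A leaf-count penalty ``gamma`` is carried in the interface for completeness
but defaults to 0 (trees are grown to a fixed small depth instead).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GBDTParams", "Tree", "TreeEnsemble", "fit_gbdt"]

_EPS = 1e-12


@dataclass(frozen=True)
class GBDTParams:
    n_trees: int = 500
    depth: int = 2
    learning_rate: float = 0.1
    l2_leaf_reg: float = 3.0
    bagging_temperature: float = 1.0
    leaf_estimation_iterations: int = 1
    gamma: float = 0.0
    min_gain: float = 1e-12
    early_stopping_rounds: int | None = 20
    validation_fraction: float = 0.1


@dataclass
class Tree:
    """Flat binary tree; node 0 is the root, children index into the arrays.

    ``feature[i] < 0`` marks node i as a leaf with score ``value[i]``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        stack = [(0, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if self.feature[node] < 0:
                out[idx] = self.value[node]
                continue
            go_left = X[idx, self.feature[node]] <= self.threshold[node]
            stack.append((self.left[node], idx[go_left]))
            stack.append((self.right[node], idx[~go_left]))
        return out

    def leaf_index(self, X: np.ndarray) -> np.ndarray:
        node = np.zeros(len(X), dtype=int)
        while True:
            internal = self.feature[node] >= 0
            if not internal.any():
                return node
            idx = np.where(internal)[0]
            f = self.feature[node[idx]]
            thr = self.threshold[node[idx]]
            go_left = X[idx, f] <= thr
            node[idx] = np.where(go_left, self.left[node[idx]], self.right[node[idx]])

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())


@dataclass
class TreeEnsemble:
    trees: list
    base_score: float
    params: GBDTParams
    n_features: int
    train_loss: list = field(default_factory=list)
    best_iteration: int | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features")
        margin = np.full(len(X), self.base_score)
        for tree in self.trees:
            margin += tree.predict(X)  # leaf values already learning-rate scaled
        return margin

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.decision_function(X)))


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _logloss(y, p, w):
    p = np.clip(p, _EPS, 1 - _EPS)
    ll = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(np.average(ll, weights=w))


def _best_split(x_sorted, order, g, u):
    """Best threshold on one pre-sorted feature by weighted variance gain.

    Residuals r = -g; gain = S_L^2/W_L + S_R^2/W_R - S^2/W with S = sum(u*r),
    W = sum(u). Returns (gain, threshold) or None.
    """
    r = -g[order]
    w = u[order]
    cs = np.cumsum(w * r)
    cw = np.cumsum(w)
    S, W = cs[-1], cw[-1]
    # candidate split after position i requires a value change at i -> i+1
    diff = np.diff(x_sorted)
    cand = np.where(diff > 0)[0]
    if len(cand) == 0:
        return None
    wl = cw[cand]
    wr = W - wl
    ok = (wl > _EPS) & (wr > _EPS)
    cand = cand[ok]
    if len(cand) == 0:
        return None
    sl = cs[cand]
    wl = cw[cand]
    gain = sl**2 / wl + (S - sl) ** 2 / (W - wl) - S**2 / W
    best = int(np.argmax(gain))
    thr = 0.5 * (x_sorted[cand[best]] + x_sorted[cand[best] + 1])
    return float(gain[best]), thr


def _grow_tree(X, g, h, u, params: GBDTParams) -> Tree:
    feature, threshold, left, right, value = [], [], [], [], []

    def new_node():
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    def leaf_value(idx):
        # Newton step on the logistic loss with L2 leaf penalty
        num = -(u[idx] * g[idx]).sum()
        den = (u[idx] * h[idx]).sum() + params.l2_leaf_reg
        return num / den if den > _EPS else 0.0

    def build(idx, depth):
        node = new_node()
        if depth >= params.depth or len(idx) < 2:
            value[node] = leaf_value(idx)
            return node
        best = None
        for j in range(X.shape[1]):
            order = idx[np.argsort(X[idx, j], kind="stable")]
            res = _best_split(X[order, j], order, g, u)
            if res is None:
                continue
            gain, thr = res
            if best is None or gain > best[0] + _EPS:
                best = (gain, j, thr)
        if best is None or best[0] <= params.min_gain:
            value[node] = leaf_value(idx)
            return node
        _, j, thr = best
        go_left = X[idx, j] <= thr
        feature[node] = j
        threshold[node] = thr
        left[node] = build(idx[go_left], depth + 1)
        right[node] = build(idx[~go_left], depth + 1)
        return node

    build(np.arange(len(X)), 0)
    return Tree(
        feature=np.asarray(feature),
        threshold=np.asarray(threshold),
        left=np.asarray(left),
        right=np.asarray(right),
        value=np.asarray(value, dtype=float),
    )


def fit_gbdt(X, y, params: GBDTParams = GBDTParams(), seed: int = 0) -> TreeEnsemble:
    """Stagewise boosting of depth-limited regression trees on logistic loss.

    With ``early_stopping_rounds`` set, a seeded ``validation_fraction``
    slice is held out of the boosting sample and boosting stops once its
    log-loss has not improved for that many stages (the ensemble is
    truncated to the best stage). Degenerate stages (no split gains) yield
    intercept-only trees.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.isnan(X).any():
        raise ValueError("X must be complete (impute first)")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    rng = np.random.default_rng(seed)
    n = len(y)

    use_val = params.early_stopping_rounds is not None and n >= 50
    if use_val:
        perm = rng.permutation(n)
        n_val = max(1, int(round(params.validation_fraction * n)))
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
    else:
        fit_idx = np.arange(n)
        val_idx = np.empty(0, dtype=int)
    Xf, yf = X[fit_idx], y[fit_idx]
    Xv, yv = X[val_idx], y[val_idx]

    pos = yf.mean()
    base = float(np.log(pos / (1 - pos))) if 0 < pos < 1 else 0.0
    margin_f = np.full(len(yf), base)
    margin_v = np.full(len(yv), base)

    trees: list[Tree] = []
    train_loss: list[float] = []
    best_val, best_iter, stall = np.inf, 0, 0
    ones = np.ones(len(yf))

    for k in range(params.n_trees):
        t = params.bagging_temperature
        if t > 0:
            u = rng.standard_exponential(len(yf)) ** t
            u /= u.mean()
        else:
            u = ones
        p = _sigmoid(margin_f)
        g = p - yf
        h = p * (1 - p)
        tree = _grow_tree(Xf, g, h, u, params)
        # refine leaf values with extra Newton iterations on updated margins
        leaf = tree.leaf_index(Xf)
        for _ in range(params.leaf_estimation_iterations - 1):
            trial = margin_f + tree.value[leaf]
            p2 = _sigmoid(trial)
            g2, h2 = p2 - yf, p2 * (1 - p2)
            for node in np.unique(leaf):
                rows = leaf == node
                den = (u[rows] * h2[rows]).sum() + params.l2_leaf_reg
                if den > _EPS:
                    tree.value[node] += -(u[rows] * g2[rows]).sum() / den
        tree.value *= params.learning_rate
        margin_f += tree.value[leaf]
        trees.append(tree)
        train_loss.append(_logloss(yf, _sigmoid(margin_f), None))

        if use_val:
            margin_v += tree.predict(Xv)
            vl = _logloss(yv, _sigmoid(margin_v), None)
            if vl < best_val - 1e-7:
                best_val, best_iter, stall = vl, k + 1, 0
            else:
                stall += 1
                if stall >= params.early_stopping_rounds:
                    break

    if use_val and best_iter > 0:
        trees = trees[:best_iter]
        train_loss = train_loss[:best_iter]

    return TreeEnsemble(
        trees=trees,
        base_score=base,
        params=params,
        n_features=X.shape[1],
        train_loss=train_loss,
        best_iteration=best_iter if use_val else None,
    )
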