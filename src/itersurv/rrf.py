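"""Guided regularized random forest for regression.

A regularized random forest (RRF) penalizes the split gain of features not
yet used anywhere in the forest: a candidate split on a new feature scores
``coef_reg * gain`` while an already-selected feature scores the raw gain.
With ``coef_reg < 1`` the forest concentrates its splits on a compact
feature set; ``coef_reg = 1`` recovers the ordinary random forest.  The
selected set is global across trees (guided-regularization convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def regularized_split_gain(
    raw_gain: float, feature: int, selected_so_far: set, coef_reg: float
) -> float:
    """Penalized gain used in split choice: raw for already-selected features,
    ``coef_reg * raw`` for new ones."""
    if raw_gain < 0:
        raise ValueError("raw_gain must be >= 0")
    if not (0 < coef_reg <= 1):
        raise ValueError("coef_reg must be in (0, 1]")
    return raw_gain if feature in selected_so_far else coef_reg * raw_gain


@dataclass
class _Node:
    feature: int = -1
    threshold: float = 0.0
    left: "_Node | None" = None
    right: "_Node | None" = None
    value: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None


@dataclass
class RegularizedRandomForest:
    """Bagged regression trees with guided feature regularization.

    Parameters
    ----------
    n_trees : number of bootstrap trees.
    mtry : features sampled per node.
    coef_reg : gain multiplier for not-yet-selected features, in (0, 1].
    min_leaf : minimum samples per child node.
    max_depth : depth cap (None = unlimited).
    seed : RNG seed; fits are deterministic given the seed.
    """

    n_trees: int = 50
    mtry: int = 2
    coef_reg: float = 0.9
    min_leaf: int = 5
    max_depth: int | None = None
    seed: int = 0

    trees_: list[_Node] = field(default_factory=list, repr=False)
    features_used_: set = field(default_factory=set, repr=False)
    oob_indices_: list[np.ndarray] = field(default_factory=list, repr=False)
    X_: np.ndarray | None = field(default=None, repr=False)
    y_: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X, y) -> "RegularizedRandomForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 2:
            raise ValueError("need at least 2 samples")
        rng = np.random.default_rng(self.seed)
        self.trees_ = []
        self.features_used_ = set()
        self.oob_indices_ = []
        mtry = min(self.mtry, p)
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = self._build(X, y, boot, depth=0, rng=rng, mtry=mtry)
            self.trees_.append(tree)
            self.oob_indices_.append(oob)
        self.X_, self.y_ = X, y
        return self

    # -- tree construction ----------------------------------------------
    def _build(self, X, y, idx, depth, rng, mtry) -> _Node:
        node = _Node(value=float(np.mean(y[idx])))
        if len(idx) < 2 * self.min_leaf:
            return node
        if self.max_depth is not None and depth >= self.max_depth:
            return node
        yi = y[idx]
        if np.ptp(yi) == 0:
            return node
        feats = rng.choice(X.shape[1], size=mtry, replace=False)
        best = (0.0, -1, 0.0)  # (penalized gain, feature, threshold)
        parent_sse = float(np.sum((yi - yi.mean()) ** 2))
        for f in feats:
            xv = X[idx, f]
            order = np.argsort(xv, kind="stable")
            xs, ys = xv[order], yi[order]
            # candidate cuts between distinct consecutive values honoring min_leaf
            csum = np.cumsum(ys)
            total = csum[-1]
            m = len(ys)
            k = np.arange(1, m)  # left child sizes
            valid = (k >= self.min_leaf) & (m - k >= self.min_leaf) & (xs[1:] != xs[:-1])
            if not valid.any():
                continue
            left_mean = csum[:-1] / k
            right_mean = (total - csum[:-1]) / (m - k)
            # SSE reduction = between-group sum of squares
            gain = k * (left_mean - yi.mean()) ** 2 + (m - k) * (right_mean - yi.mean()) ** 2
            gain = np.where(valid, gain, -np.inf)
            j = int(np.argmax(gain))
            raw = float(gain[j])
            if raw <= 0:
                continue
            pen = regularized_split_gain(raw, int(f), self.features_used_, self.coef_reg)
            if pen > best[0]:
                # gain index j corresponds to left-child size j+1, i.e. a cut
                # between xs[j] and xs[j+1]
                best = (pen, int(f), float(0.5 * (xs[j] + xs[j + 1])))
        pen, f, thr = best
        if f < 0 or pen <= 0 or parent_sse <= 0:
            return node
        self.features_used_.add(f)
        mask = X[idx, f] <= thr
        node.feature, node.threshold = f, thr
        node.left = self._build(X, y, idx[mask], depth + 1, rng, mtry)
        node.right = self._build(X, y, idx[~mask], depth + 1, rng, mtry)
        return node

    # -- prediction ------------------------------------------------------
    def _predict_tree(self, tree: _Node, X: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        stack = [(tree, np.arange(len(X)))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                out[idx] = node.value
                continue
            mask = X[idx, node.feature] <= node.threshold
            stack.append((node.left, idx[mask]))
            stack.append((node.right, idx[~mask]))
        return out

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.mean([self._predict_tree(t, X) for t in self.trees_], axis=0)

    # -- importance ------------------------------------------------------
    def oob_permutation_importance(self, seed: int = 0) -> np.ndarray:
        """Mean increase in OOB squared error when one feature is permuted."""
        if self.X_ is None:
            raise ValueError("fit first")
        X, y = self.X_, self.y_
        rng = np.random.default_rng(seed)
        n, p = X.shape
        base_pred = np.zeros(n)
        counts = np.zeros(n)
        tree_oob_preds = []
        for tree, oob in zip(self.trees_, self.oob_indices_):
            if len(oob) == 0:
                tree_oob_preds.append(None)
                continue
            pr = self._predict_tree(tree, X[oob])
            tree_oob_preds.append(pr)
            base_pred[oob] += pr
            counts[oob] += 1
        seen = counts > 0
        base_mse = float(np.mean((base_pred[seen] / counts[seen] - y[seen]) ** 2))
        imp = np.zeros(p)
        for f in range(p):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, f] = X[perm, f]
            pred = np.zeros(n)
            for tree, oob in zip(self.trees_, self.oob_indices_):
                if len(oob) == 0:
                    continue
                pred[oob] += self._predict_tree(tree, Xp[oob])
            mse = float(np.mean((pred[seen] / counts[seen] - y[seen]) ** 2))
            imp[f] = mse - base_mse
        return imp
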