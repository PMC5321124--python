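"""Survival random forest benchmark with randomized log-rank splitting.

Each tree is grown on a bootstrap sample; at every node, a few random cut
points per candidate feature are scored by the standardized two-sample
log-rank statistic and the best (feature, cut) pair wins.  Leaves carry
Nelson-Aalen cumulative hazards of their in-bag members; the ensemble
survival curve is ``S(t|x) = exp(-mean_t CHF(t|x))``, and an exact
survival time is read off as the ``q``-percent quantile of that curve with
``q`` common to all subjects (tuned by cross-validation to minimize RMSE
on uncensored subjects; the shipped default is 37).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import rmse_uncensored

log = logging.getLogger(__name__)

DEFAULT_Q = 37.0


def _logrank_batch(ts: np.ndarray, ev: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Signed standardized log-rank statistics for S candidate groupings.

    ``ts``/``ev`` are node times/events sorted ascending; ``G`` is an
    (n, S) boolean matrix of left-child membership in that order.
    Zero-variance candidates score 0.
    """
    n = len(ts)
    uniq, first = np.unique(ts, return_index=True)
    # suffix sums give at-risk counts at each unique time
    suffix_g = np.cumsum(G[::-1], axis=0)[::-1]                       # (n, S)
    n_at = n - first                                                   # (U,)
    n1_at = suffix_g[first]                                            # (U, S)
    d = np.add.reduceat(ev, first)                                     # (U,)
    d1 = np.add.reduceat(G * ev[:, None], first, axis=0)               # (U, S)
    has_event = d > 0
    d, d1 = d[has_event], d1[has_event]
    n_at, n1_at = n_at[has_event], n1_at[has_event]
    frac = n1_at / n_at[:, None]
    O = d1.sum(axis=0)
    E = (d[:, None] * frac).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_terms = (
            d[:, None]
            * frac
            * (1.0 - frac)
            * np.where(n_at > 1, (n_at - d) / np.maximum(n_at - 1, 1), 0.0)[:, None]
        )
    V = v_terms.sum(axis=0)
    stat = np.zeros(G.shape[1])
    ok = V > 0
    stat[ok] = (O[ok] - E[ok]) / np.sqrt(V[ok])
    return stat


def logrank_statistic(times, events, group, signed: bool = False) -> float:
    """Two-sample log-rank statistic |O - E| / sqrt(V) (signed on request)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=bool)
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    order = np.argsort(times, kind="stable")
    stat = _logrank_batch(times[order], events[order], group[order][:, None])[0]
    return float(stat if signed else abs(stat))


@dataclass
class _SurvNode:
    feature: int = -1
    threshold: float = 0.0
    level_set: frozenset | None = None  # categorical bipartition
    left: "_SurvNode | None" = None
    right: "_SurvNode | None" = None
    leaf_times: np.ndarray | None = None
    leaf_chf: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None


def _nelson_aalen(ts: np.ndarray, ev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(ts, kind="stable")
    ts, ev = ts[order], ev[order]
    uniq, first = np.unique(ts, return_index=True)
    n_at = len(ts) - first
    d = np.add.reduceat(ev, first)
    mask = d > 0
    return uniq[mask], np.cumsum(d[mask] / n_at[mask])


@dataclass
class SurvivalForest:
    trees: list[_SurvNode]
    grid: np.ndarray            # union of training event times
    q: float = DEFAULT_Q
    categorical: set = field(default_factory=set)

    @property
    def B(self) -> int:
        return len(self.trees)


def randomized_best_split(
    X: np.ndarray,
    ts: np.ndarray,
    ev: np.ndarray,
    candidates: np.ndarray,
    n_random_splits: int,
    min_leaf: int,
    rng: np.random.Generator,
    categorical: set = frozenset(),
    scope: str = "per_feature",
):
    """Best (feature, cut) by log-rank among random candidate cuts.

    Continuous features draw cut points uniformly over observed values;
    categorical features draw random level bipartitions, each draw counted
    against the ``n_random_splits`` budget.  Returns ``None`` when no
    candidate yields two valid children (>= min_leaf subjects and >= 1
    event each).
    """
    order = np.argsort(ts, kind="stable")
    ts_s, ev_s = ts[order], ev[order]
    cols = []
    meta = []  # (feature, threshold-or-levelset)
    if scope == "total":
        feats = rng.choice(candidates, size=n_random_splits, replace=True)
        budget_per = {f: int((feats == f).sum()) for f in set(feats.tolist())}
    elif scope == "per_feature":
        budget_per = {int(f): n_random_splits for f in candidates}
    else:
        raise ValueError(f"unknown random_splits_scope {scope!r}")
    for f, budget in budget_per.items():
        xv = X[:, f]
        vals = np.unique(xv)
        if len(vals) < 2:
            continue
        if f in categorical:
            for _ in range(budget):
                pick = vals[rng.random(len(vals)) < 0.5]
                if len(pick) == 0 or len(pick) == len(vals):
                    continue
                cols.append(np.isin(xv, pick))
                meta.append((f, frozenset(pick.tolist())))
        else:
            cuts = rng.choice(vals[:-1], size=min(budget, len(vals) - 1), replace=False)
            for c in cuts:
                cols.append(xv <= c)
                meta.append((f, float(c)))
    if not cols:
        return None
    G = np.stack(cols, axis=1)
    sizes = G.sum(axis=0)
    ev_left = (G & (ev[:, None] == 1)).sum(axis=0)
    n, n_ev = len(ts), int(ev.sum())
    valid = (
        (sizes >= min_leaf)
        & (n - sizes >= min_leaf)
        & (ev_left >= 1)
        & (n_ev - ev_left >= 1)
    )
    if not valid.any():
        return None
    stats = np.abs(_logrank_batch(ts_s, ev_s, G[order]))
    stats[~valid] = -np.inf
    best = int(np.argmax(stats))
    if not np.isfinite(stats[best]):
        return None
    return meta[best]


def _grow(X, ts, ev, idx, mtry, n_random_splits, min_leaf, rng, categorical, scope) -> _SurvNode:
    node = _SurvNode()
    if len(idx) >= 2 * min_leaf and ev[idx].sum() >= 2:
        p = X.shape[1]
        cand = rng.choice(p, size=min(mtry, p), replace=False)
        choice = randomized_best_split(
            X[idx], ts[idx], ev[idx], cand, n_random_splits, min_leaf, rng, categorical, scope
        )
        if choice is not None:
            f, cut = choice
            if isinstance(cut, frozenset):
                mask = np.isin(X[idx, f], list(cut))
                node.level_set = cut
            else:
                mask = X[idx, f] <= cut
                node.threshold = cut
            node.feature = f
            node.left = _grow(
                X, ts, ev, idx[mask], mtry, n_random_splits, min_leaf, rng, categorical, scope
            )
            node.right = _grow(
                X, ts, ev, idx[~mask], mtry, n_random_splits, min_leaf, rng, categorical, scope
            )
            return node
    node.leaf_times, node.leaf_chf = _nelson_aalen(ts[idx], ev[idx])
    return node


def fit_srf(
    X,
    times,
    events,
    B: int = 1000,
    mtry: int | None = None,
    n_random_splits: int = 10,
    min_leaf: int = 15,
    seed: int = 0,
    categorical: set | None = None,
    random_splits_scope: str = "per_feature",
    bootstrap: bool = True,
) -> SurvivalForest:
    """Grow ``B`` bootstrap survival trees with randomized log-rank splits.

    ``bootstrap=False`` grows every tree on the full sample (useful to
    audit a single tree's leaf hazards)."""
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n, p = X.shape
    if mtry is None:
        mtry = int(np.ceil(np.sqrt(p)))
    categorical = set(categorical or ())
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(B):
        boot = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        trees.append(
            _grow(
                X,
                times,
                events,
                boot,
                mtry,
                n_random_splits,
                min_leaf,
                rng,
                categorical,
                random_splits_scope,
            )
        )
    grid = np.unique(times[events == 1])
    if len(grid) == 0:
        grid = np.unique(times)
    return SurvivalForest(trees=trees, grid=grid, categorical=categorical)


def _leaf_of(tree: _SurvNode, X: np.ndarray) -> list[_SurvNode]:
    out: list[_SurvNode | None] = [None] * len(X)
    stack = [(tree, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            for i in idx:
                out[i] = node
            continue
        if node.level_set is not None:
            mask = np.isin(X[idx, node.feature], list(node.level_set))
        else:
            mask = X[idx, node.feature] <= node.threshold
        stack.append((node.left, idx[mask]))
        stack.append((node.right, idx[~mask]))
    return out


def predict_chf(forest: SurvivalForest, X) -> np.ndarray:
    """Ensemble cumulative hazard on the forest's time grid, one row per x."""
    X = np.asarray(X, dtype=float)
    total = np.zeros((len(X), len(forest.grid)))
    for tree in forest.trees:
        leaves = _leaf_of(tree, X)
        for i, leaf in enumerate(leaves):
            if len(leaf.leaf_times) == 0:
                continue
            pos = np.searchsorted(leaf.leaf_times, forest.grid, side="right")
            chf = np.concatenate([[0.0], leaf.leaf_chf])[pos]
            total[i] += chf
    return total / forest.B


def predict_survival(forest: SurvivalForest, X) -> np.ndarray:
    return np.exp(-predict_chf(forest, X))


def predict_time_quantile(forest: SurvivalForest, X, q: float | None = None) -> np.ndarray:
    """Smallest grid time t with S(t|x) <= 1 - q/100; curves that never
    cross return the largest grid time (flagged in the log)."""
    q = forest.q if q is None else q
    if not (0 < q < 100):
        raise ValueError("q must be in (0, 100)")
    S = predict_survival(forest, X)
    return quantile_times(S, forest.grid, q)


def quantile_times(S: np.ndarray, grid: np.ndarray, q: float) -> np.ndarray:
    """Read the q% survival quantile off step curves S (rows) over grid."""
    thresh = 1.0 - q / 100.0
    crossed = S <= thresh
    out = np.empty(len(S))
    never = ~crossed.any(axis=1)
    if never.any():
        log.debug("%d curves never cross S <= %.3f; capped at max grid time", never.sum(), thresh)
    first = np.argmax(crossed, axis=1)
    out = grid[np.where(never, len(grid) - 1, first)]
    return out.astype(float)


def tune_q(S: np.ndarray, grid: np.ndarray, times, events, q_grid) -> float:
    """q minimizing RMSE on uncensored subjects over held-out survival
    curves; ties break toward smaller q."""
    q_grid = sorted(float(q) for q in q_grid)
    if not q_grid:
        raise ValueError("empty q grid")
    best_q, best_rmse = None, np.inf
    for q in q_grid:
        pred = quantile_times(S, grid, q)
        r = rmse_uncensored(pred, times, events)
        if r < best_rmse:
            best_q, best_rmse = q, r
    return float(best_q)
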