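"""Base regression learners on log survival time, variable importance,
gamma-thresholded feature selection and the M-model ensemble.

Five learner kinds mirror the original toolchain: a guided regularized
random forest, support vector regression with RBF and polynomial kernels,
a quantile regression forest, and partial least squares.  Feature
selection averages the 0-100-scaled variable importances of a three-model
trio (RRF, RBF-SVR, PLS) and keeps features whose mean importance exceeds
``gamma``.  Ensemble predictions are averaged on the log scale, i.e. a
geometric mean in days.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR

from .rrf import RegularizedRandomForest

log = logging.getLogger(__name__)

KINDS = ("REGULARIZED_FOREST", "SVR_RBF", "QUANTILE_FOREST", "SVR_POLY", "PLS")

_ALLOWED_HYPERS = {
    "REGULARIZED_FOREST": {"mtry", "coefReg", "n_trees", "min_leaf", "max_depth"},
    "SVR_RBF": {"sigma", "C"},
    "QUANTILE_FOREST": {"mtry", "n_trees", "quantile", "min_leaf"},
    "SVR_POLY": {"degree", "scale", "C"},
    "PLS": {"ncomp"},
}


@dataclass(frozen=True)
class LearnerSpec:
    """A base learner: kind, hyperparameters, and its role in the pipeline."""

    kind: str
    hyperparameters: dict = field(default_factory=dict)
    role: str = "PREDICTION"  # or FEATURE_SELECTION

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown learner kind {self.kind!r}")
        unknown = set(self.hyperparameters) - _ALLOWED_HYPERS[self.kind]
        if unknown:
            raise ValueError(f"unknown hyperparameters for {self.kind}: {sorted(unknown)}")


def selection_specs() -> list[LearnerSpec]:
    """The feature-selection trio with its shipped hyperparameters."""
    return [
        LearnerSpec("REGULARIZED_FOREST", {"mtry": 2, "coefReg": 0.95}, "FEATURE_SELECTION"),
        LearnerSpec("SVR_RBF", {"sigma": 0.02, "C": 0.15}, "FEATURE_SELECTION"),
        LearnerSpec("PLS", {"ncomp": 2}, "FEATURE_SELECTION"),
    ]


def prediction_specs(stage: str = "loop") -> list[LearnerSpec]:
    """The M=5 prediction models; ``stage`` selects the shipped tuned values
    used inside the imputation loop vs the final prediction stage."""
    if stage == "loop":
        svr_rbf = {"sigma": 0.001, "C": 0.1}
        svr_poly = {"degree": 3, "scale": 0.0005, "C": 0.15}
    elif stage == "final":
        svr_rbf = {"sigma": 0.002, "C": 0.3}
        svr_poly = {"degree": 5, "scale": 0.0005, "C": 0.3}
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return [
        LearnerSpec("REGULARIZED_FOREST", {"mtry": 2, "coefReg": 0.9}),
        LearnerSpec("SVR_RBF", svr_rbf),
        LearnerSpec("QUANTILE_FOREST", {"mtry": 6}),
        LearnerSpec("SVR_POLY", svr_poly),
        LearnerSpec("PLS", {"ncomp": 2}),
    ]


class _QuantileForest:
    """Quantile regression forest: sklearn trees, per-leaf training targets,
    weighted-quantile prediction (Meinshausen's construction)."""

    def __init__(self, n_trees=100, mtry=6, quantile=0.5, min_leaf=5, seed=0):
        self.quantile = quantile
        self.min_leaf = min_leaf
        self.mtry = mtry
        self.n_trees = n_trees
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.y_ = np.asarray(y, dtype=float)
        self.rf_ = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=min(self.mtry, X.shape[1]),
            min_samples_leaf=self.min_leaf,
            random_state=self.seed,
        ).fit(X, self.y_)
        self.train_leaves_ = self.rf_.apply(X)  # (n, B)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        leaves = self.rf_.apply(X)  # (m, B)
        n, m = len(self.y_), len(X)
        order = np.argsort(self.y_, kind="stable")
        y_sorted = self.y_[order]
        W = np.zeros((m, n))
        for b in range(leaves.shape[1]):
            tl = self.train_leaves_[:, b]
            sizes = np.bincount(tl)
            match = tl[None, :] == leaves[:, b][:, None]          # (m, n)
            W += match / sizes[tl][None, :]
        W /= leaves.shape[1]
        cw = np.cumsum(W[:, order], axis=1)
        idx = np.argmax(cw >= self.quantile - 1e-12, axis=1)
        return y_sorted[np.minimum(idx, n - 1)]


class _PLSWrapper:
    def __init__(self, ncomp):
        self.ncomp = ncomp

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        ncomp = max(1, min(self.ncomp, X.shape[1], len(X) - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.pls_ = PLSRegression(n_components=ncomp, scale=False).fit(X, y)
        return self

    def predict(self, X):
        return self.pls_.predict(np.asarray(X, dtype=float)).ravel()


class _ConstantModel:
    def __init__(self, value):
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(np.asarray(X)), self.value)


def fit_base_learner(spec: LearnerSpec, X, y_log, seed: int = 0):
    """Fit one base learner on a complete numeric design and log times."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y_log, dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 training rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y_log must be finite")
    if np.ptp(y) == 0:
        return _ConstantModel(float(y[0]))
    hp = spec.hyperparameters
    if spec.kind == "REGULARIZED_FOREST":
        return RegularizedRandomForest(
            n_trees=hp.get("n_trees", 50),
            mtry=hp.get("mtry", 2),
            coef_reg=hp.get("coefReg", 0.9),
            min_leaf=hp.get("min_leaf", 5),
            max_depth=hp.get("max_depth"),
            seed=seed,
        ).fit(X, y)
    if spec.kind == "SVR_RBF":
        return SVR(kernel="rbf", gamma=hp.get("sigma", 0.002), C=hp.get("C", 0.3)).fit(X, y)
    if spec.kind == "SVR_POLY":
        return SVR(
            kernel="poly",
            degree=hp.get("degree", 5),
            gamma=hp.get("scale", 0.0005),
            coef0=1.0,
            C=hp.get("C", 0.3),
        ).fit(X, y)
    if spec.kind == "QUANTILE_FOREST":
        return _QuantileForest(
            n_trees=hp.get("n_trees", 100),
            mtry=hp.get("mtry", 6),
            quantile=hp.get("quantile", 0.5),
            min_leaf=hp.get("min_leaf", 5),
            seed=seed,
        ).fit(X, y)
    if spec.kind == "PLS":
        return _PLSWrapper(hp.get("ncomp", 2)).fit(X, y)
    raise ValueError(spec.kind)  # unreachable, kinds validated in spec


@dataclass(frozen=True)
class VariableImportance:
    """Per-feature importance min-max scaled to [0, 100]."""

    scores: dict[str, float]
    source: str

    @staticmethod
    def from_raw(raw: dict[str, float], source: str) -> "VariableImportance":
        vals = np.array(list(raw.values()), dtype=float)
        if len(vals) == 1:
            return VariableImportance({next(iter(raw)): 100.0}, source)
        if len(vals) == 0 or np.ptp(vals) == 0:
            if len(vals):
                log.warning("all raw importances equal (%s); scores set to 0", source)
            return VariableImportance({k: 0.0 for k in raw}, source)
        lo, hi = vals.min(), vals.max()
        return VariableImportance(
            {k: float(100.0 * (v - lo) / (hi - lo)) for k, v in raw.items()}, source
        )


def _smooth_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R-squared of a univariate cubic polynomial smooth of y on x."""
    if np.ptp(x) == 0:
        return 0.0
    z = (x - x.mean()) / x.std()
    design = np.column_stack([np.ones_like(z), z, z**2, z**3])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    return 0.0 if sst == 0 else 1.0 - float(np.sum(resid**2)) / sst


def variable_importance(model, spec: LearnerSpec, X: pd.DataFrame, y_log) -> VariableImportance:
    """Per-kind raw importances, min-max scaled to 0-100.

    Forest: out-of-bag permutation importance.  PLS: sum over components of
    |loading weight| x variance explained.  SVR kinds: model-free per-feature
    importance (R-squared of a univariate polynomial smooth of y on the
    feature).
    """
    names = list(X.columns)
    Xa = X.to_numpy(dtype=float)
    y = np.asarray(y_log, dtype=float)
    if isinstance(model, _ConstantModel):
        raw = {n: 0.0 for n in names}
    elif spec.kind == "REGULARIZED_FOREST":
        imp = model.oob_permutation_importance(seed=0)
        raw = {n: float(v) for n, v in zip(names, imp)}
    elif spec.kind == "PLS":
        pls = model.pls_
        W = np.abs(pls.x_weights_)  # (p, ncomp)
        t_var = np.var(pls.x_scores_, axis=0)
        q = np.abs(pls.y_loadings_.ravel())
        comp_weight = t_var * q**2
        raw_vals = W @ comp_weight
        raw = {n: float(v) for n, v in zip(names, raw_vals)}
    else:  # SVR kinds: model-free univariate smooth
        raw = {n: max(0.0, _smooth_r2(Xa[:, j], y)) for j, n in enumerate(names)}
    return VariableImportance.from_raw(raw, spec.kind)


def mean_vi(vis: list[VariableImportance]) -> dict[str, float]:
    universe = list(vis[0].scores)
    for v in vis[1:]:
        if set(v.scores) != set(universe):
            raise ValueError("VI feature universes differ")
    return {f: float(np.mean([v.scores[f] for v in vis])) for f in universe}


def mean_vi_select(
    vis: list[VariableImportance], gamma: float
) -> list[str]:
    """Features with mean VI > gamma, in descending mean-VI order (ties by
    name).  An empty selection falls back to the top max(5, sqrt(p))."""
    means = mean_vi(vis)
    ranked = sorted(means, key=lambda f: (-means[f], f))
    chosen = [f for f in ranked if means[f] > gamma]
    if not chosen:
        k = max(5, int(np.ceil(np.sqrt(len(ranked)))))
        chosen = ranked[: min(k, len(ranked))]
        log.warning("no feature exceeded gamma=%.3g; falling back to top %d", gamma, len(chosen))
    return chosen


@dataclass
class EnsembleFit:
    """Selected features plus M fitted models on log time."""

    selected_features: list[str]
    fits: list
    specs: list[LearnerSpec]


def fit_ensemble(
    X: pd.DataFrame,
    y_log,
    specs: list[LearnerSpec],
    sel_specs: list[LearnerSpec] | None = None,
    gamma: float = 24.0,
    seed: int = 0,
    selected_features: list[str] | None = None,
) -> EnsembleFit:
    """Feature-select with the trio, then fit all M prediction learners on
    the reduced design.  ``selected_features`` bypasses re-selection (used
    when refitting per fold with a fixed feature set)."""
    if selected_features is None:
        sel_specs = sel_specs or selection_specs()
        vis = []
        for i, s in enumerate(sel_specs):
            m = fit_base_learner(s, X.to_numpy(dtype=float), y_log, seed=seed + i)
            vis.append(variable_importance(m, s, X, y_log))
        selected_features = mean_vi_select(vis, gamma)
    Xr = X[selected_features]
    fits = [
        fit_base_learner(s, Xr.to_numpy(dtype=float), y_log, seed=seed + 100 + i)
        for i, s in enumerate(specs)
    ]
    return EnsembleFit(selected_features=list(selected_features), fits=fits, specs=list(specs))


def predict_ensemble(fit: EnsembleFit, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-model log predictions (n x M) and the averaged days prediction
    exp(mean log) -- the geometric mean on the day scale."""
    missing = [f for f in fit.selected_features if f not in X.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    if len(X) == 0:
        return np.empty((0, len(fit.fits))), np.empty(0)
    Xr = X[fit.selected_features].to_numpy(dtype=float)
    log_preds = np.column_stack([m.predict(Xr) for m in fit.fits])
    return log_preds, np.exp(log_preds.mean(axis=1))
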