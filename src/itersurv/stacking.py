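"""LASSO super learner over the M prediction models.

Out-of-sample log-time predictions are averaged over the I covariate
imputation streams per model, then a LASSO with log completed survival
time as the outcome picks the combination weights (plain L1 regression:
coefficients may be zero or negative, an intercept is included, and the
member columns are not re-standardized since they share the log-day
scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import Lasso, LassoCV, LinearRegression


@dataclass
class StackedModel:
    weights: np.ndarray    # M LASSO coefficients on log-time member predictions
    intercept: float
    lam: float             # L1 penalty actually used

    def predict_log(self, member_log_preds: np.ndarray) -> np.ndarray:
        Z = np.asarray(member_log_preds, dtype=float)
        return self.intercept + Z @ self.weights

    def predict_days(self, member_log_preds: np.ndarray) -> np.ndarray:
        return np.exp(self.predict_log(member_log_preds))


def average_over_imputations(preds: np.ndarray) -> np.ndarray:
    """Mean over the I streams of an (n, M, I) grid of log predictions."""
    arr = np.asarray(preds, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected an (n, M, I) array")
    if np.any(~np.isfinite(arr)):
        raise ValueError("missing cell in the M x I prediction grid")
    return arr.mean(axis=2)


def fit_stacker(
    averaged_preds: np.ndarray,
    y_log_complete: np.ndarray,
    lam: float | None = None,
    cv: int = 10,
    seed: int = 0,
) -> StackedModel:
    """LASSO on the M member columns; lambda from internal CV unless fixed.

    ``lam = 0`` falls back to OLS (and requires n > M)."""
    Z = np.asarray(averaged_preds, dtype=float)
    y = np.asarray(y_log_complete, dtype=float)
    n, M = Z.shape
    if lam == 0:
        if n <= M:
            raise ValueError("n <= M with lambda = 0 is ill-posed")
        ols = LinearRegression().fit(Z, y)
        return StackedModel(weights=ols.coef_, intercept=float(ols.intercept_), lam=0.0)
    if lam is None:
        model = LassoCV(alphas=100, cv=min(cv, n), random_state=seed, max_iter=5000)
        model.fit(Z, y)
        return StackedModel(
            weights=model.coef_, intercept=float(model.intercept_), lam=float(model.alpha_)
        )
    model = Lasso(alpha=lam, max_iter=5000).fit(Z, y)
    return StackedModel(weights=model.coef_, intercept=float(model.intercept_), lam=float(lam))


def predict_final(stacked: StackedModel, member_log_preds_per_stream: np.ndarray) -> np.ndarray:
    """New-subject prediction: average the (n, M, I) member grid over I,
    apply the LASSO weights on the log scale, exponentiate to days."""
    Z = average_over_imputations(member_log_preds_per_stream)
    if len(Z) == 0:
        return np.empty(0)
    return stacked.predict_days(Z)
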