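"""Covariate completion and transformation.

Missing covariates are completed by chained-equations multiple imputation:
predictive mean matching (PMM) for continuous columns and sampled-category
prediction for categorical columns, repeated to yield ``I`` completed
datasets.  Completed covariates are then one-hot encoded (full indicator
set, no dropped level), Box-Cox transformed with power 0.2 and
mean-variance standardized, with transform parameters fitted on training
rows only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data_model import CATEGORICAL, CONTINUOUS, SurvivalDataset

log = logging.getLogger(__name__)

BOXCOX_LAMBDA = 0.2
PMM_DONORS = 5


def boxcox(x, lam: float = BOXCOX_LAMBDA):
    """Box-Cox power transform; ``lam == 0`` is the natural log."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("Box-Cox input must be positive")
    if lam == 0:
        return np.log(x)
    return (np.power(x, lam) - 1.0) / lam


def standardize_fit_apply(
    column: np.ndarray, train_mask: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Center/scale by the train-row mean and sample sd.

    A zero-sd (constant) train column maps to all zeros rather than
    dividing by zero.
    """
    column = np.asarray(column, dtype=float)
    train = column[np.asarray(train_mask, dtype=bool)]
    mean = float(np.mean(train))
    sd = float(np.std(train, ddof=1)) if len(train) > 1 else 0.0
    if sd == 0.0:
        log.warning("constant column standardized to zeros")
        return np.zeros_like(column), mean, 0.0
    return (column - mean) / sd, mean, sd


def add_log_features(matrix: pd.DataFrame, features: list[str]) -> pd.DataFrame:
    """Append ``log_<f> = ln(f)`` for each selected strictly positive feature."""
    out = matrix.copy()
    for f in features:
        vals = out[f].to_numpy(dtype=float)
        if np.any(vals <= 0):
            raise ValueError(f"feature {f!r} has non-positive values; cannot log")
        out[f"log_{f}"] = np.log(vals)
    return out


def encode_covariates(cov: pd.DataFrame, schema: dict[str, str]) -> pd.DataFrame:
    """Numeric design matrix: continuous as float, categoricals as the full
    indicator set ``name=level`` (deterministic column order)."""
    cols: dict[str, np.ndarray] = {}
    for name in cov.columns:
        if schema[name] == CONTINUOUS:
            cols[name] = cov[name].to_numpy(dtype=float)
        else:
            series = cov[name].astype(object)
            for level in sorted({str(v) for v in series.dropna()}):
                cols[f"{name}={level}"] = (series.astype(str) == level).astype(float)
    return pd.DataFrame(cols, index=cov.index)


@dataclass
class CovariateMatrixSet:
    """``I`` completed numeric design matrices over identical rows/columns.

    ``completed`` keeps the completed raw covariate frames (pre-encoding)
    for audit; ``transform_params`` records the per-feature Box-Cox shift,
    mean and sd once :meth:`transform` has been applied.
    """

    matrices: list[pd.DataFrame]
    completed: list[pd.DataFrame]
    schema: dict[str, str]
    transform_params: dict[str, dict[str, float]] | None = field(default=None)

    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return len(self.matrices)

    @property
    def columns(self) -> list[str]:
        return list(self.matrices[0].columns)

    def continuous_columns(self) -> list[str]:
        return [c for c in self.columns if self.schema.get(c) == CONTINUOUS]

    def transform(
        self, train_mask: np.ndarray | None = None, lam: float = BOXCOX_LAMBDA
    ) -> "CovariateMatrixSet":
        """Box-Cox (power ``lam``) + standardization of continuous columns.

        Parameters are fitted on the FIRST matrix's train rows and applied
        to every matrix so the I streams stay on a common scale.  Features
        with values <= 0 are shifted by ``1 - min`` first; indicator
        columns are standardized only (no power transform).
        """
        n = len(self.matrices[0])
        mask = np.ones(n, dtype=bool) if train_mask is None else np.asarray(train_mask, bool)
        params: dict[str, dict[str, float]] = {}
        cont = set(self.continuous_columns())
        new_mats = [m.copy() for m in self.matrices]
        for colname in self.columns:
            if colname in cont:
                pooled_min = min(float(m[colname].min()) for m in new_mats)
                shift = 0.0 if pooled_min > 0 else 1.0 - pooled_min
                ref = boxcox(new_mats[0][colname].to_numpy(dtype=float) + shift, lam)
                _, mean, sd = standardize_fit_apply(ref, mask)
                for m in new_mats:
                    z = boxcox(m[colname].to_numpy(dtype=float) + shift, lam)
                    m[colname] = (z - mean) / sd if sd > 0 else 0.0
                params[colname] = {"shift": shift, "lam": lam, "mean": mean, "sd": sd}
            else:
                col = new_mats[0][colname].to_numpy(dtype=float)
                _, mean, sd = standardize_fit_apply(col, mask)
                for m in new_mats:
                    v = m[colname].to_numpy(dtype=float)
                    m[colname] = (v - mean) / sd if sd > 0 else 0.0
                params[colname] = {"shift": 0.0, "lam": 1.0, "mean": mean, "sd": sd}
        return CovariateMatrixSet(new_mats, self.completed, dict(self.schema), params)

    def apply_transform(self, cov: pd.DataFrame) -> pd.DataFrame:
        """Encode + transform new covariate rows with the fitted parameters."""
        if self.transform_params is None:
            raise ValueError("transform() has not been fitted")
        enc = encode_covariates(cov, self.schema)
        out = pd.DataFrame(0.0, index=enc.index, columns=self.columns)
        for colname in self.columns:
            p = self.transform_params[colname]
            if colname in enc.columns:
                v = enc[colname].to_numpy(dtype=float)
            else:
                v = np.zeros(len(enc))
            if p["lam"] != 1.0:
                v = boxcox(np.maximum(v + p["shift"], 1e-12), p["lam"])
            out[colname] = (v - p["mean"]) / p["sd"] if p["sd"] > 0 else 0.0
        return out


def _design_for_mice(
    completed: pd.DataFrame,
    schema: dict[str, str],
    exclude: str,
    outcome: pd.DataFrame | None,
) -> np.ndarray:
    """Predictor matrix for one chained-equations regression."""
    others = completed.drop(columns=[exclude])
    sub_schema = {c: schema[c] for c in others.columns}
    X = encode_covariates(others, sub_schema).to_numpy(dtype=float)
    if outcome is not None:
        X = np.column_stack([X, outcome.to_numpy(dtype=float)])
    # center/scale for numerical stability of the linear solves
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _pmm_impute_column(
    col: pd.Series,
    X: np.ndarray,
    rng: np.random.Generator,
    donors: int,
) -> pd.Series:
    obs = col.notna().to_numpy()
    y = col.to_numpy(dtype=float)
    Xo = np.column_stack([np.ones(obs.sum()), X[obs]])
    Xm = np.column_stack([np.ones((~obs).sum()), X[~obs]])
    beta, *_ = np.linalg.lstsq(Xo, y[obs], rcond=None)
    pred_obs = Xo @ beta
    pred_mis = Xm @ beta
    # donor draw: one of the `donors` observed values whose predicted mean
    # is closest to the missing cell's predicted mean
    order = np.argsort(np.abs(pred_obs[None, :] - pred_mis[:, None]), axis=1)
    pool = order[:, : min(donors, obs.sum())]
    pick = rng.integers(0, pool.shape[1], size=pool.shape[0])
    donated = y[obs][pool[np.arange(len(pick)), pick]]
    out = col.copy()
    out.loc[~obs] = donated
    return out


def _sample_categorical_column(
    col: pd.Series,
    X: np.ndarray,
    rng: np.random.Generator,
) -> pd.Series:
    obs = col.notna().to_numpy()
    levels = sorted({str(v) for v in col.dropna()})
    out = col.copy()
    if len(levels) == 1:
        out.loc[~obs] = levels[0]
        return out
    y_obs = col[obs].astype(str).to_numpy()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf = LogisticRegression(max_iter=200)
            clf.fit(X[obs], y_obs)
            proba = clf.predict_proba(X[~obs])
            classes = clf.classes_
    except Exception:  # degenerate fits fall back to the marginal draw
        counts = pd.Series(y_obs).value_counts()
        classes = counts.index.to_numpy()
        proba = np.tile(counts.to_numpy() / counts.sum(), ((~obs).sum(), 1))
    cum = np.cumsum(proba, axis=1)
    u = rng.random(len(cum))
    idx = (u[:, None] > cum).sum(axis=1).clip(max=len(classes) - 1)
    out.loc[~obs] = classes[idx]
    return out


def impute_covariates_mice(
    dataset: SurvivalDataset,
    I: int = 5,
    n_cycles: int = 5,
    seed: int = 0,
    donors: int = PMM_DONORS,
    include_outcome: bool = True,
    fit_mask: np.ndarray | None = None,
) -> CovariateMatrixSet:
    """Chained-equations multiple imputation of missing covariates.

    Each of the ``I`` streams is an independent chained-equations run
    seeded from ``seed + stream``.  Each incomplete column is regressed on
    all other covariates plus, by default, log follow-up time and the
    event indicator; continuous targets use predictive mean matching over
    ``donors`` nearest observed donors, categorical targets sample a level
    from a multinomial-logistic fit.  Observed cells are never altered.

    ``fit_mask`` restricts the rows whose covariates inform the
    regressions (leakage-averse mode); all rows are always completed.
    """
    if I < 1:
        raise ValueError("I must be >= 1")
    cov = dataset.covariates.copy()
    fully_missing = [c for c in cov.columns if cov[c].isna().all()]
    if fully_missing:
        raise ValueError(f"columns 100% missing, cannot initialize: {fully_missing}")
    schema = dataset.schema
    outcome = None
    if include_outcome:
        outcome = pd.DataFrame(
            {"_logtime": np.log(dataset.times), "_event": dataset.events}
        )
    incomplete = [c for c in cov.columns if cov[c].isna().any()]
    incomplete.sort(key=lambda c: cov[c].isna().mean())

    completed_frames: list[pd.DataFrame] = []
    for m in range(I):
        rng = np.random.default_rng(seed + m)
        work = cov.copy()
        # initialize: random observed draws (keeps PMM range property from cycle 0)
        for c in incomplete:
            miss = work[c].isna()
            donors_init = work.loc[~miss, c].to_numpy()
            work.loc[miss, c] = rng.choice(donors_init, size=int(miss.sum()))
            if schema[c] == CONTINUOUS:
                work[c] = pd.to_numeric(work[c])
        for _ in range(n_cycles if incomplete else 0):
            for c in incomplete:
                target = cov[c].copy()  # original missingness pattern
                work_c = work.copy()
                work_c[c] = target
                X = _design_for_mice(work_c, schema, c, outcome)
                if fit_mask is not None:
                    miss_rows = target.isna().to_numpy()
                    keep = np.asarray(fit_mask, bool) | miss_rows
                    target = target[keep].reset_index(drop=True)
                    X = X[keep]
                    if schema[c] == CONTINUOUS:
                        filled = _pmm_impute_column(target, X, rng, donors)
                    else:
                        filled = _sample_categorical_column(target, X, rng)
                    work.loc[np.flatnonzero(keep)[target.isna().to_numpy()], c] = (
                        filled[target.isna().to_numpy()].to_numpy()
                    )
                else:
                    if schema[c] == CONTINUOUS:
                        work[c] = _pmm_impute_column(target, X, rng, donors)
                    else:
                        work[c] = _sample_categorical_column(target, X, rng)
        completed_frames.append(work)

    matrices = [encode_covariates(f, schema) for f in completed_frames]
    # harmonize columns across streams (a rare level may be absent in one draw)
    all_cols: list[str] = []
    for m in matrices:
        for c in m.columns:
            if c not in all_cols:
                all_cols.append(c)
    matrices = [m.reindex(columns=all_cols, fill_value=0.0) for m in matrices]
    enc_schema = dict(schema)
    for c in all_cols:
        if c not in enc_schema:
            enc_schema[c] = CATEGORICAL
    return CovariateMatrixSet(matrices, completed_frames, enc_schema)
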