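"""Survival-model evaluation: Kaplan-Meier curves, time-dependent AUC,
integrated AUC (iAUC), and RMSE restricted to uncensored subjects.

The time-dependent AUC is the cumulative/dynamic variant with inverse
probability-of-censoring weights (IPCW) from the Kaplan-Meier estimate of
the censoring distribution: at horizon t, "cases" are subjects who died by
t and "controls" are subjects still at risk beyond t.  The iAUC averages
AUC(t) over the observed event times up to a horizon tau, weighted by the
KM-estimated event-time density, giving a single number in [0, 1] that is
invariant to monotone transforms of the risk scores.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

from .data_model import FoldIndex, SurvivalDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate with Greenwood standard errors."""

    times: np.ndarray        # sorted distinct event times
    survival: np.ndarray     # S(t) at those times (right-continuous steps)
    se: np.ndarray           # Greenwood standard error of S(t)
    at_risk: np.ndarray
    events: np.ndarray

    def at(self, t, left: bool = False):
        """Step-function evaluation; ``left=True`` gives the left limit S(t-).
        Returns a scalar for scalar ``t``, an array otherwise."""
        scalar = np.isscalar(t) or np.ndim(t) == 0
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.times) == 0:  # no events anywhere: S is identically 1
            out = np.ones_like(t)
        else:
            side = "left" if left else "right"
            idx = np.searchsorted(self.times, t, side=side)
            out = np.where(idx == 0, 1.0, self.survival[np.maximum(idx - 1, 0)])
        return float(out[0]) if scalar else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "TIME": self.times,
                "SURVIVAL": self.survival,
                "SE": self.se,
                "AT_RISK": self.at_risk,
                "EVENTS": self.events,
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator (via lifelines' event table)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table.iloc[1:] if 0.0 in kmf.event_table.index else kmf.event_table
    mask = table["observed"] > 0
    t = table.index.to_numpy(dtype=float)[mask.to_numpy()]
    d = table["observed"].to_numpy(dtype=float)[mask.to_numpy()]
    n = table["at_risk"].to_numpy(dtype=float)[mask.to_numpy()]
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: var S(t) = S(t)^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw = np.cumsum(np.where(n > d, d / (n * (n - d)), 0.0))
    se = surv * np.sqrt(gw)
    return KMCurve(times=t, survival=surv, se=se, at_risk=n, events=d)


def censoring_km(times, events) -> KMCurve:
    """KM estimate of the censoring distribution (event roles flipped)."""
    events = np.asarray(events, dtype=int)
    return km_estimate(times, 1 - events)


def td_auc(scores, times, events, t, censor_curve: KMCurve | None = None) -> float:
    """Cumulative/dynamic time-dependent AUC at horizon ``t`` with IPCW.

    ``scores`` are risk scores, higher = shorter survival.  Returns NaN
    when there is no case or no control at ``t`` (the point is then
    excluded from integration by :func:`iauc`).
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if censor_curve is None:
        censor_curve = censoring_km(times, events)
    cases = (times <= t) & (events == 1)
    controls = times > t
    if cases.sum() == 0 or controls.sum() == 0:
        log.debug("AUC undefined at t=%g (no cases or controls)", t)
        return float("nan")
    G = censor_curve.at(times[cases], left=True)
    G = np.maximum(G, 1e-12)
    w = 1.0 / G
    sc, sk = scores[cases], scores[controls]
    gt = (sc[:, None] > sk[None, :]).sum(axis=1)
    ties = (sc[:, None] == sk[None, :]).sum(axis=1)
    conc = gt + 0.5 * ties
    return float((w * conc).sum() / (w.sum() * controls.sum()))


def iauc(
    scores,
    times,
    events,
    t_grid=None,
    tau: float | None = None,
) -> float:
    """Event-density-weighted integral of AUC(t) over the time grid.

    Defaults: grid = distinct observed event times up to ``tau`` (90th
    percentile of follow-up); weights = KM event-time mass S(t-) - S(t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    curve = km_estimate(times, events)
    if tau is None:
        tau = float(np.quantile(times, 0.9))
    if t_grid is None:
        t_grid = curve.times[curve.times <= tau]
    t_grid = np.asarray(t_grid, dtype=float)
    if len(t_grid) == 0:
        raise ValueError("empty time grid")
    cc = censoring_km(times, events)
    aucs = np.array([td_auc(scores, times, events, t, cc) for t in t_grid])
    mass = curve.at(t_grid, left=True) - curve.at(t_grid)
    mass = np.where(mass > 0, mass, 0.0)
    # grid points off the event grid carry no KM mass; weight them equally
    if mass.sum() == 0:
        mass = np.ones_like(t_grid)
    ok = np.isfinite(aucs) & (mass > 0)
    if not ok.any():
        raise ValueError("AUC undefined on the whole grid")
    return float((aucs[ok] * mass[ok]).sum() / mass[ok].sum())


def rmse_uncensored(predicted_days, observed_days, events) -> float:
    """RMSE over uncensored subjects only; censored subjects are excluded."""
    pred = np.asarray(predicted_days, dtype=float)
    obs = np.asarray(observed_days, dtype=float)
    ev = np.asarray(events, dtype=int)
    if not (len(pred) == len(obs) == len(ev)):
        raise ValueError("length mismatch")
    mask = ev == 1
    if mask.sum() == 0:
        raise ValueError("no uncensored subjects")
    return float(np.sqrt(np.mean((pred[mask] - obs[mask]) ** 2)))


@dataclass
class MetricReport:
    """Pooled cross-validated metrics plus per-fold diagnostics."""

    iauc: float
    rmse_uncensored: float | None
    per_fold: dict[int, dict[str, float]] = field(default_factory=dict)
    settings: dict = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        payload = {
            "iauc": self.iauc,
            "rmse_uncensored": self.rmse_uncensored,
            "per_fold": {str(k): v for k, v in self.per_fold.items()},
            "settings": self.settings,
        }
        return json.dumps(payload, sort_keys=True, **kwargs)


def cross_validate(
    dataset: SurvivalDataset,
    fit_predict: Callable[[SurvivalDataset, SurvivalDataset], np.ndarray],
    folds: FoldIndex | None = None,
    tau: float | None = None,
) -> MetricReport:
    """Pooled k-fold cross-validation of any fit/predict pipeline.

    ``fit_predict(train, test)`` returns predicted survival days for the
    test subjects.  Held-out predictions are pooled and scored once
    (pooled, not fold-averaged); per-fold RMSEs are kept for diagnostics.
    """
    folds = folds or dataset.folds
    if folds is None:
        raise ValueError("dataset has no fold index")
    pred = np.full(dataset.n, np.nan)
    fold_arr = np.array([folds.assignment[i] for i in dataset.ids])
    per_fold: dict[int, dict[str, float]] = {}
    for f in range(1, folds.k + 1):
        test_mask = fold_arr == f
        train = dataset.subset(~test_mask)
        test = dataset.subset(test_mask)
        if test.events.sum() == 0:
            log.warning("fold %d has zero events; metrics pooled anyway", f)
        pred[test_mask] = np.asarray(fit_predict(train, test), dtype=float)
        if test.events.sum() > 0:
            per_fold[f] = {
                "rmse_uncensored": rmse_uncensored(
                    pred[test_mask], test.times, test.events
                )
            }
    if np.any(~np.isfinite(pred)):
        raise ValueError("non-finite held-out predictions")
    overall_iauc = iauc(-pred, dataset.times, dataset.events, tau=tau)
    overall_rmse = (
        rmse_uncensored(pred, dataset.times, dataset.events)
        if dataset.events.sum() > 0
        else None
    )
    return MetricReport(
        iauc=overall_iauc,
        rmse_uncensored=overall_rmse,
        per_fold=per_fold,
        settings={"k": folds.k, "seed": folds.seed, "tau": tau},
    )
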