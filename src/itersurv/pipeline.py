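"""End-to-end orchestration: covariate completion -> per-stream iterative
outcome imputation -> final per-model out-of-fold predictions -> LASSO
super learner -> metrics.

Every random draw descends from the single ``seed`` in the config, so a
run is fully reproducible from its manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import SurvivalDataset
from .evaluation import MetricReport, iauc, rmse_uncensored
from .imputation_engine import (
    CompletedOutcome,
    ImputationConfig,
    ImputationTrace,
    default_config,
    run_iterative_imputation,
)
from .learners import (
    EnsembleFit,
    LearnerSpec,
    fit_ensemble,
    predict_ensemble,
    prediction_specs,
    selection_specs,
)
from .preprocessing import CovariateMatrixSet, impute_covariates_mice
from .stacking import StackedModel, average_over_imputations, fit_stacker

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; serialized into the manifest."""

    I: int = 5
    mice_cycles: int = 5
    folds_k: int = 10
    gamma: float = 24.0
    tau: float | None = None
    stack_lambda: float | None = None  # None = internal CV choice
    stack_cv: int = 10
    seed: int = 0
    alpha_by_study: dict[str, float] | None = None  # None = shipped defaults
    alpha_star: float = 80.0
    iauc_gain_threshold: float = 0.2
    k_max: int = 5
    loop_specs: list[LearnerSpec] = field(default_factory=lambda: prediction_specs("loop"))
    final_specs: list[LearnerSpec] = field(default_factory=lambda: prediction_specs("final"))
    sel_specs: list[LearnerSpec] = field(default_factory=selection_specs)
    fit_full_members: bool = False  # also fit M x I members on all rows (for new-data predict)

    def imputation_config(self, studies, seed_offset: int = 0) -> ImputationConfig:
        kwargs = dict(
            alpha_star=self.alpha_star,
            iauc_gain_threshold=self.iauc_gain_threshold,
            k_max=self.k_max,
            seed=self.seed + seed_offset,
        )
        if self.alpha_by_study is not None:
            return ImputationConfig(alpha_by_study=dict(self.alpha_by_study), **kwargs)
        return default_config(studies, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key in ("loop_specs", "final_specs", "sel_specs"):
            if key in d:
                d[key] = [
                    LearnerSpec(
                        s["kind"], dict(s.get("hyperparameters", {})), s.get("role", "PREDICTION")
                    )
                    for s in d[key]
                ]
        return cls(**d)

    def manifest(self) -> dict:
        def spec_dict(s: LearnerSpec) -> dict:
            return {"kind": s.kind, "hyperparameters": dict(s.hyperparameters), "role": s.role}

        return {
            "I": self.I,
            "mice_cycles": self.mice_cycles,
            "folds_k": self.folds_k,
            "gamma": self.gamma,
            "tau": self.tau,
            "stack_lambda": self.stack_lambda,
            "stack_cv": self.stack_cv,
            "seed": self.seed,
            "alpha_by_study": self.alpha_by_study,
            "alpha_star": self.alpha_star,
            "iauc_gain_threshold": self.iauc_gain_threshold,
            "k_max": self.k_max,
            "loop_specs": [spec_dict(s) for s in self.loop_specs],
            "final_specs": [spec_dict(s) for s in self.final_specs],
            "sel_specs": [spec_dict(s) for s in self.sel_specs],
        }


@dataclass
class PipelineResult:
    stacked: StackedModel
    member_log_preds: np.ndarray           # (n, M, I) out-of-fold
    predictions_days: np.ndarray           # final stacked predictions, training rows
    outcomes: list[CompletedOutcome]       # per stream
    traces: list[ImputationTrace]
    features: list[list[str]]              # per stream final feature set
    matrix_set: CovariateMatrixSet
    metrics: MetricReport
    manifest: dict
    step1_outcomes: list[CompletedOutcome] = field(default_factory=list)
    full_member_fits: list[list[EnsembleFit]] | None = None  # [stream][model]


def _oof_member_predictions(
    dataset: SurvivalDataset,
    matrix: pd.DataFrame,
    y_log: np.ndarray,
    specs: list[LearnerSpec],
    features: list[str],
    seed: int,
) -> np.ndarray:
    """(n, M) out-of-fold log predictions with a fixed feature set."""
    fold_arr = np.array([dataset.folds.assignment[i] for i in dataset.ids])
    out = np.full((dataset.n, len(specs)), np.nan)
    for f in range(1, dataset.folds.k + 1):
        test = fold_arr == f
        fit_f = fit_ensemble(
            matrix.loc[~test],
            y_log[~test],
            specs,
            seed=seed + f,
            selected_features=features,
        )
        log_preds, _ = predict_ensemble(fit_f, matrix.loc[test])
        out[test] = log_preds
    return out


def run_pipeline(dataset: SurvivalDataset, config: PipelineConfig) -> PipelineResult:
    """Run the full training pipeline on one dataset.

    Returns per-subject final predictions (from out-of-fold member
    predictions, so a subject's prediction never uses a model that saw its
    own outcome) plus the stacked model and audit artifacts.
    """
    ds = dataset if dataset.folds is not None else dataset.with_folds(config.folds_k, config.seed)
    mats = impute_covariates_mice(
        ds, I=config.I, n_cycles=config.mice_cycles, seed=config.seed
    ).transform()
    from .imputation_engine import initial_impute  # local to avoid cycle confusion

    outcomes, traces, features_per_stream, step1 = [], [], [], []
    member = np.full((ds.n, len(config.final_specs), mats.I), np.nan)
    for m in range(mats.I):
        imp_cfg = config.imputation_config(ds.studies, seed_offset=1 + m)
        rng0 = np.random.default_rng(imp_cfg.seed)
        step1.append(initial_impute(ds, imp_cfg, rng0))
        outcome, trace, feats = run_iterative_imputation(
            ds,
            mats.matrices[m],
            imp_cfg,
            config.loop_specs,
            config.sel_specs,
            gamma=config.gamma,
            tau=config.tau,
        )
        outcomes.append(outcome)
        traces.append(trace)
        features_per_stream.append(feats)
        y_log = np.log(outcome.y_new.loc[ds.ids].to_numpy())
        member[:, :, m] = _oof_member_predictions(
            ds, mats.matrices[m], y_log, config.final_specs, feats,
            seed=config.seed + 1000 * (m + 1),
        )
    # stacking target: per-subject mean over streams of log completed time
    y_log_stack = np.mean(
        [np.log(o.y_new.loc[ds.ids].to_numpy()) for o in outcomes], axis=0
    )
    Z = average_over_imputations(member)
    stacked = fit_stacker(
        Z, y_log_stack, lam=config.stack_lambda, cv=config.stack_cv, seed=config.seed
    )
    pred_days = stacked.predict_days(Z)
    metrics = MetricReport(
        iauc=iauc(-pred_days, ds.times, ds.events, tau=config.tau),
        rmse_uncensored=(
            rmse_uncensored(pred_days, ds.times, ds.events) if ds.events.sum() else None
        ),
        per_fold={},
        settings={"k": ds.folds.k, "seed": config.seed, "tau": config.tau},
    )
    full_fits = None
    if config.fit_full_members:
        full_fits = []
        for m in range(mats.I):
            y_log = np.log(outcomes[m].y_new.loc[ds.ids].to_numpy())
            fits_m = [
                fit_ensemble(
                    mats.matrices[m],
                    y_log,
                    [spec],
                    seed=config.seed + 5000 + 10 * m + j,
                    selected_features=features_per_stream[m],
                )
                for j, spec in enumerate(config.final_specs)
            ]
            full_fits.append(fits_m)
    return PipelineResult(
        stacked=stacked,
        member_log_preds=member,
        predictions_days=pred_days,
        outcomes=outcomes,
        traces=traces,
        features=features_per_stream,
        matrix_set=mats,
        metrics=metrics,
        manifest={"config": config.manifest()},
        step1_outcomes=step1,
        full_member_fits=full_fits,
    )


def run_step1_baseline(dataset: SurvivalDataset, config: PipelineConfig) -> np.ndarray:
    """Comparator: the same ensemble + stacker trained on step-I-only
    completed outcomes (covariate-free imputation, no iterative
    adjustment).  Returns final stacked predictions in days."""
    from .imputation_engine import initial_impute

    ds = dataset if dataset.folds is not None else dataset.with_folds(config.folds_k, config.seed)
    mats = impute_covariates_mice(
        ds, I=config.I, n_cycles=config.mice_cycles, seed=config.seed
    ).transform()
    member = np.full((ds.n, len(config.final_specs), mats.I), np.nan)
    y_logs = []
    for m in range(mats.I):
        imp_cfg = config.imputation_config(ds.studies, seed_offset=1 + m)
        outcome = initial_impute(ds, imp_cfg, np.random.default_rng(imp_cfg.seed))
        y_log = np.log(outcome.y_new.loc[ds.ids].to_numpy())
        y_logs.append(y_log)
        fit_sel = fit_ensemble(
            mats.matrices[m], y_log, config.final_specs, config.sel_specs,
            gamma=config.gamma, seed=config.seed + m,
        )
        member[:, :, m] = _oof_member_predictions(
            ds, mats.matrices[m], y_log, config.final_specs, fit_sel.selected_features,
            seed=config.seed + 2000 * (m + 1),
        )
    Z = average_over_imputations(member)
    stacked = fit_stacker(
        Z, np.mean(y_logs, axis=0), lam=config.stack_lambda, cv=config.stack_cv, seed=config.seed
    )
    return stacked.predict_days(Z)


def predict_new(result: PipelineResult, covariates: pd.DataFrame) -> np.ndarray:
    """Predicted survival days for new subjects' raw covariates."""
    if result.full_member_fits is None:
        raise ValueError("pipeline was run without fit_full_members=True")
    enc = result.matrix_set.apply_transform(covariates)
    I = len(result.full_member_fits)
    M = len(result.full_member_fits[0])
    member = np.empty((len(enc), M, I))
    for m in range(I):
        for j in range(M):
            log_preds, _ = predict_ensemble(result.full_member_fits[m][j], enc)
            member[:, j, m] = log_preds[:, 0]
    Z = average_over_imputations(member)
    return result.stacked.predict_days(Z)


def save_metrics(metrics: MetricReport, path) -> None:
    with open(path, "w") as fh:
        fh.write(metrics.to_json(indent=2))
        fh.write("\n")
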