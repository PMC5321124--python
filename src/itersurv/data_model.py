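"""Core survival-data containers, CSV I/O and reproducible fold assignment.

A dataset is one row per subject: an opaque ``ID``, a ``STUDY`` label, a
follow-up time in days (``TIME``), an event indicator (``EVENT``, 1 = death
observed, 0 = right-censored), followed by an arbitrary block of mixed
continuous/categorical covariates in which empty cells denote missing
values.  Missing covariates are preserved as ``NaN`` and never silently
filled here; covariate completion lives in :mod:`itersurv.preprocessing`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("ID", "STUDY", "TIME", "EVENT")

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: days per month used for any month-based display
DAYS_PER_MONTH = 30.4375


class DataValidationError(ValueError):
    """Raised when a dataset violates the row-level contract."""


@dataclass(frozen=True)
class FoldIndex:
    """Reproducible assignment of subject ids to cross-validation folds."""

    k: int
    assignment: Mapping[str, int]
    seed: int

    def fold_of(self, subject_id: str) -> int:
        return self.assignment[subject_id]

    def members(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f == fold]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"ID": list(self.assignment), "FOLD": list(self.assignment.values())}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class SurvivalDataset:
    """Subjects with (time, event, study, covariates) plus an optional fold index.

    ``frame`` holds the reserved columns followed by covariates; ``schema``
    maps every covariate name to ``"continuous"`` or ``"categorical"``.
    """

    frame: pd.DataFrame
    schema: dict[str, str]
    folds: FoldIndex | None = field(default=None)

    def __post_init__(self) -> None:
        _validate_frame(self.frame)
        missing = [c for c in self.covariate_names if c not in self.schema]
        if missing:
            raise DataValidationError(f"schema does not cover covariates: {missing}")

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["ID"].to_numpy()

    @property
    def studies(self) -> np.ndarray:
        return self.frame["STUDY"].to_numpy()

    @property
    def times(self) -> np.ndarray:
        return self.frame["TIME"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.frame["EVENT"].to_numpy(dtype=int)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in RESERVED_COLUMNS]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame[self.covariate_names]

    def missing_fraction(self) -> pd.Series:
        """Per-covariate fraction of missing cells."""
        return self.covariates.isna().mean()

    def censored_mask(self) -> np.ndarray:
        return self.events == 0

    # -- folds -----------------------------------------------------------
    def with_folds(self, k: int, seed: int, method: str = "balanced") -> "SurvivalDataset":
        return replace(self, folds=assign_folds(list(self.ids), k, seed, method=method))

    def subset(self, mask: np.ndarray) -> "SurvivalDataset":
        sub = self.frame.loc[np.asarray(mask)].reset_index(drop=True)
        return SurvivalDataset(sub, dict(self.schema), self.folds)


def _validate_frame(frame: pd.DataFrame) -> None:
    for col in RESERVED_COLUMNS:
        if col not in frame.columns:
            raise DataValidationError(f"missing reserved column {col!r}")
    times = pd.to_numeric(frame["TIME"], errors="coerce")
    bad = frame.index[~(times > 0)].tolist()
    if bad:
        raise DataValidationError(f"non-positive or unparseable TIME in rows {bad}")
    events = pd.to_numeric(frame["EVENT"], errors="coerce")
    bad = frame.index[~events.isin([0, 1])].tolist()
    if bad:
        raise DataValidationError(f"EVENT not in {{0,1}} in rows {bad}")
    dup = frame["ID"][frame["ID"].duplicated()].tolist()
    if dup:
        raise DataValidationError(f"duplicate ID values: {dup}")


def infer_schema(
    covariates: pd.DataFrame, hints: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Declare each covariate continuous when numeric-parseable, else categorical."""
    hints = dict(hints or {})
    schema: dict[str, str] = {}
    for col in covariates.columns:
        if col in hints:
            kind = hints[col]
            if kind not in (CONTINUOUS, CATEGORICAL):
                raise DataValidationError(f"unknown kind {kind!r} for column {col!r}")
            schema[col] = kind
            continue
        observed = covariates[col].dropna()
        numeric = pd.to_numeric(observed, errors="coerce")
        schema[col] = CONTINUOUS if len(observed) and numeric.notna().all() else CATEGORICAL
    return schema


def load_dataset(
    path: str | Path, schema_hints: Mapping[str, str] | None = None
) -> SurvivalDataset:
    """Read a subject-level CSV (header ID, STUDY, TIME, EVENT, covariates...).

    Empty cells are missing.  Rows violating the contract (non-positive
    time, event outside {0,1}, duplicate id) raise
    :class:`DataValidationError` naming the offending rows.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": np.nan})
    _validate_frame(raw)
    frame = raw.copy()
    frame["TIME"] = pd.to_numeric(frame["TIME"])
    frame["EVENT"] = pd.to_numeric(frame["EVENT"]).astype(int)
    cov = frame[[c for c in frame.columns if c not in RESERVED_COLUMNS]]
    schema = infer_schema(cov, schema_hints)
    for col, kind in schema.items():
        if kind == CONTINUOUS:
            frame[col] = pd.to_numeric(frame[col])
    return SurvivalDataset(frame, schema)


def write_dataset(dataset: SurvivalDataset, path: str | Path) -> None:
    dataset.frame.to_csv(path, index=False, na_rep="")


def assign_folds(
    ids: Sequence[str], k: int, seed: int, method: str = "balanced"
) -> FoldIndex:
    """Uniform random fold assignment, deterministic given ``seed``.

    ``balanced`` (default) shuffles ids and deals them round-robin so fold
    sizes differ by at most one; ``iid`` draws each fold label
    independently and uniformly.
    """
    ids = list(ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(set(ids)) != len(ids):
        raise ValueError("ids must be distinct")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds number of subjects n={len(ids)}")
    rng = np.random.default_rng(seed)
    if method == "balanced":
        order = rng.permutation(len(ids))
        folds = {ids[j]: (pos % k) + 1 for pos, j in enumerate(order)}
    elif method == "iid":
        draws = rng.integers(1, k + 1, size=len(ids))
        folds = {i: int(f) for i, f in zip(ids, draws)}
    else:
        raise ValueError(f"unknown fold method {method!r}")
    return FoldIndex(k=k, assignment=folds, seed=seed)


def write_predictions(
    ids: Sequence[str], predicted_times: Iterable[float], path: str | Path
) -> None:
    """Two-column CSV (ID, PREDICTED_TIME_DAYS) preserving input order."""
    times = np.asarray(list(predicted_times), dtype=float)
    ids = list(ids)
    if len(ids) != len(times):
        raise ValueError(f"{len(ids)} ids but {len(times)} predictions")
    if np.any(times <= 0):
        raise ValueError("predicted times must be positive")
    pd.DataFrame({"ID": ids, "PREDICTED_TIME_DAYS": times}).to_csv(path, index=False)


def read_predictions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"ID": str})
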