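"""Leakage-safe grid-search cross-validation over damage regressors.

Oversampling is applied inside each fold, after the train/validation
split, and only to the training portion — validation folds never contain
synthetic records.  The same harness runs the PGNN and all baseline
algorithms so their CV scores are directly comparable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.ensemble import (
    AdaBoostRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from ..errors import ConfigurationError, InsufficientDataError
from ..synthetic_data import DoERecord
from ._metrics import records_to_xy
from ._pgnn import ModelConfig, train_pgnn
from ._resample import MinorityRegionSpec, identify_minority_region, smote_oversample

__all__ = [
    "BASELINE_ALGORITHMS",
    "SklearnPredictor",
    "fit_model",
    "FoldAudit",
    "GridPointResult",
    "GridSearchResult",
    "grid_search_cv",
]

BASELINE_ALGORITHMS = (
    "linear",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "adaboost",
    "svr",
)


class SklearnPredictor:
    """Adapter giving sklearn estimators the clipped-predict contract."""

    def __init__(self, estimator):
        self.estimator = estimator

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.clip(np.asarray(self.estimator.predict(X), dtype=float), 0.0, 100.0)


def _make_estimator(algorithm: str, params: dict, seed: int):
    p = dict(params)
    if algorithm == "linear":
        return LinearRegression(**p)
    if algorithm == "decision_tree":
        return DecisionTreeRegressor(random_state=seed, **p)
    if algorithm == "random_forest":
        return RandomForestRegressor(random_state=seed, **p)
    if algorithm == "gradient_boosting":
        return GradientBoostingRegressor(random_state=seed, **p)
    if algorithm == "adaboost":
        return AdaBoostRegressor(random_state=seed, **p)
    if algorithm == "svr":
        return make_pipeline(StandardScaler(), SVR(**p))
    raise ConfigurationError(f"unknown algorithm {algorithm!r}")


def fit_model(
    algorithm: str,
    records: Sequence[DoERecord],
    params: dict | None = None,
    seed: int = 0,
):
    """Fit one algorithm on records, returning a clipped predictor."""
    params = params or {}
    if algorithm == "pgnn":
        config = replace(ModelConfig(seed=seed), **params)
        return train_pgnn(records, config)
    X, y = records_to_xy(records)
    est = _make_estimator(algorithm, params, seed)
    est.fit(X, y)
    return SklearnPredictor(est)


@dataclass(frozen=True)
class FoldAudit:
    """Provenance bookkeeping for one (grid point, fold) training run."""

    grid_index: int
    fold: int
    n_train_real: int
    n_train_synthetic: int
    n_val: int
    n_val_synthetic: int


@dataclass
class GridPointResult:
    params: dict
    fold_rmses: list[float]
    mean_rmse: float


@dataclass
class GridSearchResult:
    best_params: dict
    best_score: float
    table: list[GridPointResult]
    audit: list[FoldAudit] = field(default_factory=list)


def _grid_points(grid: dict) -> list[dict]:
    if not grid:
        raise ConfigurationError("hyperparameter grid must be non-empty")
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search_cv(
    algorithm: str,
    records: Sequence[DoERecord],
    grid: dict,
    n_folds: int = 5,
    spec: MinorityRegionSpec | None = None,
    seed: int = 0,
) -> GridSearchResult:
    """K-fold grid search with per-fold oversampling of the training split.

    Folds partition the records; each fold's training portion is augmented
    by ``smote_oversample`` while the validation portion stays raw.  The
    winner has the lowest mean validation RMSE (ties: fewer
    hyperparameters, then lexicographic parameter order).
    """
    if n_folds < 2:
        raise ConfigurationError("n_folds must be >= 2")
    records = list(records)
    n = len(records)
    if n < n_folds:
        raise InsufficientDataError(f"{n} records cannot form {n_folds} folds")
    spec = spec or MinorityRegionSpec()
    points = _grid_points(grid)

    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), n_folds)
    if any(len(f) < 2 for f in folds):
        raise InsufficientDataError("a fold has fewer than 2 records")

    table: list[GridPointResult] = []
    audit: list[FoldAudit] = []
    for gi, params in enumerate(points):
        fold_rmses = []
        for fi, val_idx in enumerate(folds):
            val = [records[i] for i in val_idx]
            train = [records[i] for j, f in enumerate(folds) if j != fi for i in f]
            mask = identify_minority_region(train, spec)
            augmented = smote_oversample(train, mask, spec, seed=seed * 1000 + fi)
            audit.append(
                FoldAudit(
                    grid_index=gi,
                    fold=fi,
                    n_train_real=sum(not r.synthetic for r in augmented),
                    n_train_synthetic=sum(r.synthetic for r in augmented),
                    n_val=len(val),
                    n_val_synthetic=sum(r.synthetic for r in val),
                )
            )
            predictor = fit_model(algorithm, augmented, params, seed=seed)
            Xv, yv = records_to_xy(val)
            rmse = float(np.sqrt(np.mean((predictor.predict(Xv) - yv) ** 2)))
            fold_rmses.append(rmse)
        table.append(GridPointResult(params, fold_rmses, float(np.mean(fold_rmses))))

    def sort_key(gp: GridPointResult):
        return (gp.mean_rmse, len(gp.params), sorted(map(repr, gp.params.items())))

    best = min(table, key=sort_key)
    return GridSearchResult(
        best_params=best.params, best_score=best.mean_rmse, table=table, audit=audit
    )
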