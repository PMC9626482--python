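"""Evaluation metrics for fitted damage predictors."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..errors import InsufficientDataError
from ..synthetic_data import DoERecord

__all__ = ["FitResult", "evaluate_model", "records_to_xy"]


def records_to_xy(records: Sequence[DoERecord]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array(
        [[r.params.voltage, r.params.frequency, r.params.flow, r.params.time] for r in records]
    )
    y = np.array([r.damage for r in records])
    return X, y


@dataclass
class FitResult:
    """Held-out evaluation scores plus optional CV context."""

    r2: float
    rmse: float
    mae: float
    n_test: int
    cv_scores: list[float] | None = None
    best_params: dict | None = None

    def to_dict(self) -> dict:
        return {
            "r2": None if np.isnan(self.r2) else self.r2,
            "rmse": self.rmse,
            "mae": self.mae,
            "n_test": self.n_test,
            "cv_scores": self.cv_scores,
            "best_params": self.best_params,
        }


def evaluate_model(predictor, test_records: Sequence[DoERecord]) -> FitResult:
    """R^2, RMSE and MAE of a predictor on unaugmented test records.

    Refuses synthetic (oversampled) records: evaluation is only meaningful
    on real observations.  Zero target variance yields R^2 = NaN with a
    warning rather than an error.
    """
    if not test_records:
        raise InsufficientDataError("empty test set")
    if any(r.synthetic for r in test_records):
        raise ValueError("test set contains synthetic (oversampled) records")
    X, y = records_to_xy(test_records)
    yhat = np.asarray(predictor.predict(X), dtype=float).ravel()
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("zero variance in test targets; R^2 undefined", UserWarning)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return FitResult(r2=r2, rmse=rmse, mae=mae, n_test=len(test_records))
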