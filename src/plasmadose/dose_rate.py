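"""Dose-rate extraction, 1-D K-means clustering and cluster summaries.

For each dose--damage point the damage predictor is inverted in time at a
fixed plasma operating point; the dose rate is then dose / t_irr (Gy/s).
Reachable rates are clustered with Lloyd K-means (best of several seeded
restarts, ascending relabeling) and each cluster is summarized after
Tukey 1.5*IQR outlier removal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, UnreachableTargetError
from .itf import ITFQuery, InversionSettings, find_irradiation_time
from .synthetic_data import DoseDamagePoint

__all__ = [
    "DoseRateEstimate",
    "ClusterSummary",
    "extract_dose_rates",
    "kmeans_1d",
    "treat_outliers_and_summarize",
    "cluster_estimates",
    "estimates_to_frame",
    "write_estimates_csv",
]


@dataclass
class DoseRateEstimate:
    """One inverted point: dose_rate = dose / t_irr when reachable."""

    voltage: float
    frequency: float
    flow: float
    point: DoseDamagePoint
    t_irr: float = float("nan")
    dose_rate: float = float("nan")
    reachable: bool = False
    reason: str | None = None          # unreachable code when not reachable
    cluster: int | None = None


@dataclass
class ClusterSummary:
    """Centroid and spread of one cluster after outlier removal."""

    label: int
    centroid: float          # Gy/s, mean of retained members
    std: float               # Gy/s, sample std (ddof=1; 0 for one member)
    count_before: int
    count_after: int
    removed: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "centroid_Gy_per_s": self.centroid,
            "std_Gy_per_s": self.std,
            "count_before": self.count_before,
            "count_after": self.count_after,
            "removed_Gy_per_s": self.removed,
        }


def extract_dose_rates(
    predictor,
    voltage: float,
    frequency: float,
    flow: float,
    db: Sequence[DoseDamagePoint],
    settings: InversionSettings | None = None,
) -> list[DoseRateEstimate]:
    """Invert every database point at one plasma operating point.

    Unreachable targets are flagged with their failure code, never
    dropped; reachable estimates satisfy dose_rate * t_irr = dose exactly.
    """
    if not db:
        raise InsufficientDataError("empty dose-damage database")
    settings = settings or InversionSettings()
    estimates: list[DoseRateEstimate] = []
    for point in db:
        est = DoseRateEstimate(voltage, frequency, flow, point)
        query = ITFQuery(
            voltage,
            frequency,
            flow,
            target_damage=point.damage,
            t_min=settings.t_min,
            t_max=settings.t_max,
            tolerance=settings.tolerance,
        )
        try:
            t_irr = find_irradiation_time(
                predictor,
                query,
                grid_points=settings.grid_points,
                time_resolution=settings.time_resolution,
            )
        except UnreachableTargetError as err:
            est.reason = err.code
        else:
            est.t_irr = t_irr
            est.dose_rate = point.dose / t_irr
            est.reachable = True
        estimates.append(est)
    return estimates


def _lloyd(values: np.ndarray, centroids: np.ndarray, max_iter: int = 300):
    labels = np.zeros(len(values), dtype=int)
    for _ in range(max_iter):
        new_labels = np.argmin(np.abs(values[:, None] - centroids[None, :]), axis=1)
        for c in range(len(centroids)):
            members = values[new_labels == c]
            if members.size:
                centroids[c] = members.mean()
            else:
                # empty cluster: reseed at the point farthest from its centroid
                far = int(np.argmax(np.abs(values - centroids[new_labels])))
                centroids[c] = values[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    wcss = float(np.sum((values - centroids[labels]) ** 2))
    return labels, centroids, wcss


def kmeans_1d(
    values: Sequence[float], k: int, restarts: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd K-means on scalars, best of ``restarts`` seeded initializations.

    Centroids are returned sorted ascending with labels relabeled to match,
    so label 0 is always the lowest-dose-rate cluster.
    """
    values = np.asarray(values, dtype=float)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(values):
        raise ConfigurationError(f"k={k} exceeds the number of values ({len(values)})")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, restarts)):
        init_idx = rng.choice(len(values), size=k, replace=False)
        labels, centroids, wcss = _lloyd(values.copy(), values[init_idx].astype(float))
        if best is None or wcss < best[2]:
            best = (labels, centroids, wcss)
    labels, centroids, _ = best
    order = np.argsort(centroids)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[labels], centroids[order]


def treat_outliers_and_summarize(
    values: Sequence[float], labels: Sequence[int], k: int
) -> list[ClusterSummary]:
    """Per cluster: Tukey 1.5*IQR removal, then mean and sample std.

    Quartiles use linear interpolation.  If removal would empty a cluster
    the original members are retained with a warning — an empty summary is
    never emitted.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise ConfigurationError("values and labels must have equal length")
    summaries: list[ClusterSummary] = []
    for c in range(k):
        members = values[labels == c]
        if members.size == 0:
            raise ConfigurationError(f"cluster {c} has no members")
        q1, q3 = np.percentile(members, [25, 75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        keep = (members >= lo) & (members <= hi)
        if not keep.any():
            warnings.warn(
                f"outlier removal would empty cluster {c}; retaining original members",
                UserWarning,
            )
            keep = np.ones_like(keep)
        retained = members[keep]
        removed = members[~keep]
        std = float(retained.std(ddof=1)) if retained.size > 1 else 0.0
        summaries.append(
            ClusterSummary(
                label=c,
                centroid=float(retained.mean()),
                std=std,
                count_before=int(members.size),
                count_after=int(retained.size),
                removed=[float(x) for x in removed],
            )
        )
    return summaries


def cluster_estimates(
    estimates: Sequence[DoseRateEstimate],
    k: int = 4,
    restarts: int = 10,
    seed: int = 0,
) -> tuple[list[DoseRateEstimate], list[ClusterSummary]]:
    """Cluster the reachable estimates in place and summarize the clusters.

    ``k`` is capped at the number of reachable estimates.
    """
    reachable = [e for e in estimates if e.reachable]
    if not reachable:
        raise InsufficientDataError("no reachable estimates to cluster")
    rates = np.array([e.dose_rate for e in reachable])
    k_eff = min(k, len(rates))
    labels, _ = kmeans_1d(rates, k_eff, restarts=restarts, seed=seed)
    for e, lab in zip(reachable, labels):
        e.cluster = int(lab)
    summaries = treat_outliers_and_summarize(rates, labels, k_eff)
    return list(estimates), summaries


def estimates_to_frame(estimates: Sequence[DoseRateEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "radiation_type": [e.point.radiation_type for e in estimates],
            "study_id": [e.point.study_id for e in estimates],
            "dose_Gy": [e.point.dose for e in estimates],
            "damage_pct": [e.point.damage for e in estimates],
            "t_irr_s": [e.t_irr for e in estimates],
            "dose_rate_Gy_per_s": [e.dose_rate for e in estimates],
            "cluster": [e.cluster if e.cluster is not None else -1 for e in estimates],
            "reachable": [e.reachable for e in estimates],
            "reason": [e.reason or "" for e in estimates],
        }
    )


def write_estimates_csv(
    estimates: Sequence[DoseRateEstimate],
    path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write reachable estimates; unreachable points go to a sidecar CSV."""
    df = estimates_to_frame(estimates)
    keep = df[df["reachable"]].drop(columns=["reachable", "reason"])
    keep.to_csv(path, index=False, lineterminator="\n")
    if sidecar_path is not None:
        side = df[~df["reachable"]].drop(
            columns=["reachable", "t_irr_s", "dose_rate_Gy_per_s", "cluster"]
        )
        side.to_csv(sidecar_path, index=False, lineterminator="\n")
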