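"""Train/test splitting, minority-region detection and SMOTE-style
oversampling for a continuous regression target.

Rarity is defined on the damage values themselves: records whose damage
falls in sparsely populated histogram bins form the minority region, and
synthetic records are convex combinations of nearest neighbours in the
standardized joint (features, damage) space.  Synthetic records carry a
provenance flag so leakage into validation folds is auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from ..errors import ConfigurationError, InsufficientDataError, OversamplingWarning
from ..synthetic_data import DoERecord, ProcessParams

__all__ = ["split_data", "MinorityRegionSpec", "identify_minority_region", "smote_oversample"]


def split_data(
    records: list[DoERecord], train_fraction: float = 0.75, seed: int = 0
) -> tuple[list[DoERecord], list[DoERecord]]:
    """Shuffled disjoint train/test partition; train size = round(n * fraction)."""
    if not (0.0 < train_fraction < 1.0):
        raise ConfigurationError("train_fraction must be in (0, 1)")
    n = len(records)
    if n < 4:
        raise InsufficientDataError(f"need at least 4 records to split, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_fraction))
    train = [records[i] for i in perm[:n_train]]
    test = [records[i] for i in perm[n_train:]]
    return train, test


@dataclass(frozen=True)
class MinorityRegionSpec:
    """How the rare-damage region is found and how much it is oversampled."""

    bin_width: float = 5.0          # % damage per histogram bin
    threshold: float = 0.3          # fraction of the modal bin count
    short_time_cutoff: float = 10.0  # s; descriptive short-time stratum bound
    k_neighbors: int = 5
    minority_factor: float = 5.0    # minority count multiplied by this
    majority_factor: float | None = None  # None: balance to augmented minority

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be > 0")
        if not (0.0 < self.threshold <= 1.0):
            raise ConfigurationError("threshold must be in (0, 1]")
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if self.minority_factor < 1:
            raise ConfigurationError("minority_factor must be >= 1")
        if self.majority_factor is not None and self.majority_factor < 1:
            raise ConfigurationError("majority_factor must be >= 1")


def identify_minority_region(
    records: list[DoERecord], spec: MinorityRegionSpec
) -> np.ndarray:
    """Boolean mask of records whose damage lies in a rare histogram bin.

    A bin is rare when its count is strictly below
    ``threshold * (modal bin count)``.
    """
    if not records:
        raise InsufficientDataError("empty record list")
    damages = np.array([r.damage for r in records])
    bins = np.floor(damages / spec.bin_width).astype(int)
    # damage == 100 falls on the right edge; fold it into the last full bin
    top = int(np.floor(100.0 / spec.bin_width))
    bins = np.minimum(bins, top - 1) if 100.0 % spec.bin_width == 0 else bins
    uniq, counts = np.unique(bins, return_counts=True)
    modal = counts.max()
    rare_bins = set(uniq[counts < spec.threshold * modal])
    return np.array([b in rare_bins for b in bins])


def _joint_matrix(records: list[DoERecord]) -> np.ndarray:
    return np.array(
        [
            [r.params.voltage, r.params.frequency, r.params.flow, r.params.time, r.damage]
            for r in records
        ]
    )


def _interpolate_group(
    rows: np.ndarray, z: np.ndarray, n_new: int, k: int, rng: np.random.Generator
) -> np.ndarray:
    """SMOTE-style interpolation within one group.

    New rows are x_i + u * (x_j - x_i) with u ~ U(0, 1) and j one of the k
    nearest neighbours of i inside the group (standardized distances).
    """
    m = len(rows)
    if m == 1:
        warnings.warn(
            "region has a single record; duplicating it instead of interpolating",
            OversamplingWarning,
        )
        return np.repeat(rows, n_new, axis=0)
    d2 = ((z[:, None, :] - z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    k_eff = min(k, m - 1)
    nn = np.argsort(d2, axis=1)[:, :k_eff]
    out = np.empty((n_new, rows.shape[1]))
    for s in range(n_new):
        i = int(rng.integers(m))
        j = int(nn[i, rng.integers(k_eff)])
        u = rng.uniform()
        out[s] = rows[i] + u * (rows[j] - rows[i])
    return out


def smote_oversample(
    records: list[DoERecord],
    minority_mask: np.ndarray,
    spec: MinorityRegionSpec,
    seed: int = 0,
) -> list[DoERecord]:
    """Augment minority records and counterbalance the majority region.

    Originals are always retained; synthetic records are flagged
    ``synthetic=True``.  With both factors effectively 1 the input is
    returned unchanged.
    """
    if len(minority_mask) != len(records):
        raise ConfigurationError("mask length must match records")
    rng = np.random.default_rng(seed)
    joint = _joint_matrix(records)
    sd = joint.std(axis=0)
    sd[sd == 0] = 1.0
    z = (joint - joint.mean(axis=0)) / sd

    min_idx = np.flatnonzero(minority_mask)
    maj_idx = np.flatnonzero(~minority_mask)
    n_min, n_maj = len(min_idx), len(maj_idx)

    new_rows: list[np.ndarray] = []
    n_new_min = int(round((spec.minority_factor - 1.0) * n_min))
    if n_new_min > 0 and n_min > 0:
        new_rows.append(
            _interpolate_group(joint[min_idx], z[min_idx], n_new_min, spec.k_neighbors, rng)
        )
    if spec.majority_factor is None:
        target_maj = int(round(spec.minority_factor * n_min))
        n_new_maj = max(0, target_maj - n_maj)
    else:
        n_new_maj = int(round((spec.majority_factor - 1.0) * n_maj))
    if n_new_maj > 0 and n_maj > 0:
        new_rows.append(
            _interpolate_group(joint[maj_idx], z[maj_idx], n_new_maj, spec.k_neighbors, rng)
        )

    out = list(records)
    for block in new_rows:
        for row in block:
            v, f, q, t, d = row
            out.append(
                DoERecord(
                    ProcessParams(float(v), float(f), float(q), max(0.0, float(t))),
                    float(np.clip(d, 0.0, 100.0)),
                    synthetic=True,
                )
            )
    return out
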