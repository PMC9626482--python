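"""Parameter sweeps of lowest-cluster dose rates and reference comparison.

For each (voltage, frequency) cell of a sweep grid, dose rates are
extracted, clustered, and the centroid of the lowest-rate cluster is
recorded.  Deviation grids and per-type summaries compare those centroids
against user-configured reference dose rates.  Reference values must be
supplied by the user; none ship with the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError
from .dose_rate import cluster_estimates, extract_dose_rates
from .itf import InversionSettings
from .synthetic_data import DoseDamagePoint

__all__ = [
    "SweepGrid",
    "TypeComparison",
    "parameter_sweep",
    "relative_deviation_grid",
    "comparison_summary",
    "sweep_to_frame",
    "write_sweep_csv",
    "plot_deviation_heatmap",
]


@dataclass
class SweepGrid:
    """Lowest-cluster centroid per (voltage, frequency) cell.

    ``centroids[i, j]`` corresponds to voltages[i] x frequencies[j];
    undefined cells (all targets unreachable) are NaN, never zero.
    ``lowest_min`` holds the minimum member rate of the lowest cluster.
    """

    voltages: np.ndarray
    frequencies: np.ndarray
    flow: float
    centroids: np.ndarray
    lowest_min: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.voltages), len(self.frequencies))
        if self.centroids.shape != expected or self.lowest_min.shape != expected:
            raise ConfigurationError("grid shape must be |voltages| x |frequencies|")


@dataclass
class TypeComparison:
    """Deviation metrics of one radiation type against its reference rate."""

    radiation_type: str
    reference: float           # Gy/s
    min_deviation: float
    avg_deviation: float
    ratio: float               # min lowest-cluster rate across sweep / reference

    def to_dict(self) -> dict:
        return {
            "radiation_type": self.radiation_type,
            "reference_Gy_per_s": self.reference,
            "min_relative_deviation": self.min_deviation,
            "avg_relative_deviation": self.avg_deviation,
            "min_rate_over_reference": self.ratio,
        }


def parameter_sweep(
    predictor,
    db: Sequence[DoseDamagePoint],
    voltages: Sequence[float],
    frequencies: Sequence[float],
    flow: float,
    k: int = 4,
    restarts: int = 10,
    seed: int = 0,
    settings: InversionSettings | None = None,
) -> SweepGrid:
    """Run extract -> cluster -> summarize at every (V, f) cell."""
    if not len(voltages) or not len(frequencies):
        raise ConfigurationError("sweep grids must be non-empty")
    if not db:
        raise InsufficientDataError("empty database for sweep")
    voltages = np.asarray(voltages, dtype=float)
    frequencies = np.asarray(frequencies, dtype=float)
    centroids = np.full((len(voltages), len(frequencies)), np.nan)
    lowest_min = np.full_like(centroids, np.nan)
    for i, v in enumerate(voltages):
        for j, f in enumerate(frequencies):
            estimates = extract_dose_rates(predictor, v, f, flow, db, settings)
            reachable = [e for e in estimates if e.reachable]
            if not reachable:
                continue  # undefined cell stays NaN
            try:
                _, summaries = cluster_estimates(
                    estimates, k=k, restarts=restarts, seed=seed
                )
            except InsufficientDataError as err:  # pragma: no cover - guarded above
                raise InsufficientDataError(f"cell (V={v}, f={f}): {err}") from err
            lowest = summaries[0]
            centroids[i, j] = lowest.centroid
            lowest_min[i, j] = min(
                e.dose_rate for e in reachable if e.cluster == lowest.label
            )
    return SweepGrid(voltages, frequencies, float(flow), centroids, lowest_min)


def relative_deviation_grid(sweep: SweepGrid, reference: float) -> np.ndarray:
    """Cellwise |estimate - reference| / reference; NaN cells propagate."""
    if reference <= 0:
        raise ConfigurationError("reference dose rate must be > 0")
    return np.abs(sweep.centroids - reference) / reference


def comparison_summary(
    sweeps: dict[str, SweepGrid], references: dict[str, float]
) -> dict[str, TypeComparison]:
    """Min/mean relative deviation and min-rate ratio per radiation type.

    Types whose sweep has no defined cell are excluded with a warning.
    """
    out: dict[str, TypeComparison] = {}
    for rtype, sweep in sweeps.items():
        if rtype not in references:
            raise ConfigurationError(f"no reference dose rate configured for {rtype!r}")
        ref = references[rtype]
        dev = relative_deviation_grid(sweep, ref)
        if np.all(np.isnan(dev)):
            warnings.warn(
                f"all sweep cells undefined for {rtype!r}; excluded from comparison",
                UserWarning,
            )
            continue
        out[rtype] = TypeComparison(
            radiation_type=rtype,
            reference=ref,
            min_deviation=float(np.nanmin(dev)),
            avg_deviation=float(np.nanmean(dev)),
            ratio=float(np.nanmin(sweep.lowest_min) / ref),
        )
    return out


def sweep_to_frame(sweep: SweepGrid, values: np.ndarray | None = None) -> pd.DataFrame:
    """Grid as a table: rows = voltage (kV), columns = frequency (kHz)."""
    data = sweep.centroids if values is None else values
    df = pd.DataFrame(
        data,
        index=pd.Index(sweep.voltages, name="voltage_kV"),
        columns=[f"{f:g}_kHz" for f in sweep.frequencies],
    )
    return df


def write_sweep_csv(
    sweep: SweepGrid, path: str | Path, values: np.ndarray | None = None
) -> None:
    sweep_to_frame(sweep, values).to_csv(path, lineterminator="\n")


def plot_deviation_heatmap(
    sweep: SweepGrid, deviations: np.ndarray, path: str | Path, title: str = ""
) -> None:
    """Heat map of the relative-deviation grid (frequency x voltage)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    im = ax.imshow(deviations, aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(sweep.frequencies)))
    ax.set_xticklabels([f"{f:g}" for f in sweep.frequencies], rotation=90, fontsize=7)
    ax.set_yticks(range(len(sweep.voltages)))
    ax.set_yticklabels([f"{v:g}" for v in sweep.voltages], fontsize=7)
    ax.set_xlabel("frequency (kHz)")
    ax.set_ylabel("voltage (kV)")
    if title:
        ax.set_title(title, fontsize=9)
    fig.colorbar(im, ax=ax, label="relative deviation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
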