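"""Seeded synthetic data generators.

Two kinds of tables are produced:

* a design-of-experiments (DoE) table of plasma operating points
  (voltage kV, frequency kHz, feed-gas flow slm, irradiation time s)
  with a measured % DNA damage response, and
* a dose--DNA-damage database of literature-style points
  (radiation type, study id, absorbed dose Gy, % damage).

The noise-free damage kinetics are a saturating exponential

    D(t) = d_max * (1 - exp(-k * t)),
    k    = k0 * (V/V_ref)^a_v * (f/f_ref)^a_f * (Q/Q_ref)^a_q,

linear at short times and saturating later, with a rate that grows with
voltage and frequency.  Literature studies use the same functional form in
dose with a per-study sensitivity drawn from a configurable mixture, which
produces several distinct dose-rate groups downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "ProcessParams",
    "KineticsConfig",
    "DoERecord",
    "DoELevels",
    "DoseDamagePoint",
    "LiteratureDBConfig",
    "RADIATION_TYPES",
    "DOE_COLUMNS",
    "DB_COLUMNS",
    "true_damage",
    "rate_constant",
    "KineticsPredictor",
    "generate_doe_dataset",
    "generate_literature_db",
    "doe_to_frame",
    "doe_from_frame",
    "write_doe_csv",
    "read_doe_csv",
    "db_to_frame",
    "db_from_frame",
    "write_db_csv",
    "read_db_csv",
]

RADIATION_TYPES = ("gamma", "xray", "proton", "ion", "alpha", "electron", "uv")

DOE_COLUMNS = ["voltage_kV", "frequency_kHz", "flow_slm", "time_s", "damage_pct"]
DB_COLUMNS = ["radiation_type", "study_id", "dose_Gy", "damage_pct"]


@dataclass(frozen=True)
class ProcessParams:
    """One plasma operating point.

    Attributes
    ----------
    voltage : float
        Applied voltage, kV (> 0).
    frequency : float
        Driving frequency, kHz (> 0).
    flow : float
        Feed-gas flow, slm (> 0).
    time : float
        Irradiation time, s (>= 0).
    """

    voltage: float
    frequency: float
    flow: float
    time: float

    def __post_init__(self) -> None:
        for name in ("voltage", "frequency", "flow"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ConfigurationError(f"{name} must be finite and > 0, got {v!r}")
        if not math.isfinite(self.time) or self.time < 0:
            raise ConfigurationError(f"time must be finite and >= 0, got {self.time!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.voltage, self.frequency, self.flow, self.time])


@dataclass(frozen=True)
class KineticsConfig:
    """Ground-truth kinetics for the synthetic DoE response."""

    k0: float = 0.02            # 1/s at the reference operating point
    ref_voltage: float = 8.0    # kV
    ref_frequency: float = 1.0  # kHz
    ref_flow: float = 2.0       # slm
    alpha_v: float = 2.0
    alpha_f: float = 1.0
    alpha_q: float = 0.5
    d_max: float = 100.0        # % saturation level
    noise_sd: float = 2.0       # % additive Gaussian noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.k0 > 0 and math.isfinite(self.k0)):
            raise ConfigurationError(f"k0 must be > 0, got {self.k0!r}")
        if not (0 < self.d_max <= 100):
            raise ConfigurationError(f"d_max must be in (0, 100], got {self.d_max!r}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd!r}")
        for name in ("ref_voltage", "ref_frequency", "ref_flow"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")


@dataclass(frozen=True)
class DoERecord:
    """One DoE observation: operating point plus observed % damage."""

    params: ProcessParams
    damage: float
    synthetic: bool = False  # provenance flag: True for oversampled records

    def __post_init__(self) -> None:
        if not (0.0 <= self.damage <= 100.0):
            raise ConfigurationError(f"damage must be in [0, 100], got {self.damage!r}")


@dataclass(frozen=True)
class DoELevels:
    """Factor levels of the full-factorial design."""

    voltages: tuple[float, ...] = (7.0, 8.0, 9.0, 10.0, 11.0)
    frequencies: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0)
    flows: tuple[float, ...] = (1.0, 2.0, 3.0)
    times: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0, 40.0, 60.0)

    def __post_init__(self) -> None:
        for name in ("voltages", "frequencies", "flows", "times"):
            if len(getattr(self, name)) == 0:
                raise ConfigurationError(f"at least one level required for {name}")


def rate_constant(
    kinetics: KineticsConfig,
    voltage: np.ndarray | float,
    frequency: np.ndarray | float,
    flow: np.ndarray | float,
) -> np.ndarray | float:
    """Effective first-order damage rate k(V, f, Q), 1/s."""
    v = np.asarray(voltage, dtype=float)
    f = np.asarray(frequency, dtype=float)
    q = np.asarray(flow, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ConfigurationError("voltage must be finite and > 0")
    if np.any(~np.isfinite(f)) or np.any(f <= 0):
        raise ConfigurationError("frequency must be finite and > 0")
    if np.any(~np.isfinite(q)) or np.any(q <= 0):
        raise ConfigurationError("flow must be finite and > 0")
    k = (
        kinetics.k0
        * (v / kinetics.ref_voltage) ** kinetics.alpha_v
        * (f / kinetics.ref_frequency) ** kinetics.alpha_f
        * (q / kinetics.ref_flow) ** kinetics.alpha_q
    )
    return k if k.ndim else float(k)


def true_damage(params: ProcessParams, kinetics: KineticsConfig) -> float:
    """Noise-free % damage at an operating point.

    Strictly increasing in time, bounded by ``d_max``; zero at t = 0.
    """
    k = rate_constant(kinetics, params.voltage, params.frequency, params.flow)
    return float(kinetics.d_max * -np.expm1(-k * params.time))


class KineticsPredictor:
    """Ground-truth kinetics wrapped in the fitted-predictor contract.

    ``predict`` maps an (n, 4) array of [voltage, frequency, flow, time]
    rows to % damage.  Used as a noise-free stand-in for a trained model
    in tests and oracles.
    """

    def __init__(self, kinetics: KineticsConfig | None = None):
        self.kinetics = kinetics or KineticsConfig()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k = rate_constant(self.kinetics, X[:, 0], X[:, 1], X[:, 2])
        d = self.kinetics.d_max * -np.expm1(-np.asarray(k) * X[:, 3])
        return np.clip(d, 0.0, 100.0)


def generate_doe_dataset(
    levels: DoELevels,
    kinetics: KineticsConfig,
    replicates: int = 3,
    seed: int | None = None,
) -> list[DoERecord]:
    """Full factorial of ``levels`` x ``replicates`` with noisy damage.

    Damage is ``true_damage`` plus Gaussian noise (sd ``kinetics.noise_sd``),
    truncated to [0, 100].  Identical ``seed`` reproduces the table exactly.
    """
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    rng = np.random.default_rng(kinetics.seed if seed is None else seed)
    records: list[DoERecord] = []
    for v in levels.voltages:
        for f in levels.frequencies:
            for q in levels.flows:
                for t in levels.times:
                    p = ProcessParams(v, f, q, t)
                    d0 = true_damage(p, kinetics)
                    for _ in range(replicates):
                        d = d0 + rng.normal(0.0, kinetics.noise_sd) if kinetics.noise_sd > 0 else d0
                        records.append(DoERecord(p, float(np.clip(d, 0.0, 100.0))))
    return records


# ---------------------------------------------------------------------------
# Literature-style dose--DNA-damage database
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseDamagePoint:
    """One (radiation type, study, dose, damage) literature-style datum.

    ``component`` records which sensitivity-mixture component generated the
    point (provenance for cluster-recovery checks); it is not part of the
    on-disk schema unless explicitly requested.
    """

    radiation_type: str
    study_id: int
    dose: float
    damage: float
    component: int | None = None

    def __post_init__(self) -> None:
        if self.radiation_type not in RADIATION_TYPES:
            raise ConfigurationError(f"unknown radiation type {self.radiation_type!r}")
        if not (self.dose > 0 and math.isfinite(self.dose)):
            raise ConfigurationError(f"dose must be > 0, got {self.dose!r}")
        if not (0.0 <= self.damage <= 100.0):
            raise ConfigurationError(f"damage must be in [0, 100], got {self.damage!r}")


@dataclass(frozen=True)
class LiteratureDBConfig:
    """Mixture model of per-study damage-per-Gy sensitivities.

    Each study draws a sensitivity beta (%/Gy) from a log-normal mixture:
    component ``c`` has median ``component_means[c]`` and log-space spread
    ``component_sigmas[c]``.  Damage follows a saturating curve in dose,
    damage(dose) = cap * (1 - exp(-beta * dose / cap)), sampled on a
    (log-spaced by default) dose grid, plus truncated Gaussian noise.

    The default component medians are placeholders chosen to be separated
    by a factor of 10 so that downstream dose-rate clustering has four
    well-separated groups; they are not literature values.
    """

    radiation_types: tuple[str, ...] = ("gamma", "xray", "proton", "ion")
    studies_per_type: int = 12
    component_means: tuple[float, ...] = (0.05, 0.5, 5.0, 50.0)  # %/Gy, placeholders
    component_sigmas: tuple[float, ...] = (0.15, 0.15, 0.15, 0.15)
    component_weights: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    dose_min: float = 1.0     # Gy
    dose_max: float = 1000.0  # Gy
    n_doses: int = 12
    log_spaced: bool = True
    cap: float = 100.0        # % saturation
    noise_sd: float = 0.5     # % additive noise
    seed: int = 0

    def __post_init__(self) -> None:
        if any(t not in RADIATION_TYPES for t in self.radiation_types):
            raise ConfigurationError("unknown radiation type in config")
        if self.studies_per_type < 1:
            raise ConfigurationError("studies_per_type must be >= 1")
        if any(b <= 0 for b in self.component_means):
            raise ConfigurationError("all sensitivity medians must be > 0")
        if not (
            len(self.component_means)
            == len(self.component_sigmas)
            == len(self.component_weights)
        ):
            raise ConfigurationError("mixture component lists must have equal length")
        if abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise ConfigurationError("component weights must sum to 1")
        if not (0 < self.dose_min < self.dose_max):
            raise ConfigurationError("dose grid requires 0 < dose_min < dose_max")
        if self.n_doses < 1:
            raise ConfigurationError("n_doses must be >= 1")
        if not (0 < self.cap <= 100):
            raise ConfigurationError("cap must be in (0, 100]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")


def _dose_grid(config: LiteratureDBConfig) -> np.ndarray:
    if config.log_spaced:
        return np.geomspace(config.dose_min, config.dose_max, config.n_doses)
    return np.linspace(config.dose_min, config.dose_max, config.n_doses)


def generate_literature_db(config: LiteratureDBConfig) -> list[DoseDamagePoint]:
    """Generate the synthetic dose--DNA-damage database.

    For each radiation type and study: pick a mixture component, draw the
    study sensitivity beta, and emit saturating damage over the dose grid.
    Noise-free damage is non-decreasing in dose within a study; all outputs
    are reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    doses = _dose_grid(config)
    weights = np.asarray(config.component_weights)
    points: list[DoseDamagePoint] = []
    study_id = 0
    for rtype in config.radiation_types:
        for _ in range(config.studies_per_type):
            comp = int(rng.choice(len(weights), p=weights))
            beta = config.component_means[comp] * float(
                np.exp(rng.normal(0.0, config.component_sigmas[comp]))
            )
            clean = config.cap * -np.expm1(-beta * doses / config.cap)
            if config.noise_sd > 0:
                noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape)
            else:
                noisy = clean
            noisy = np.clip(noisy, 0.0, 100.0)
            for dose, dmg in zip(doses, noisy):
                points.append(
                    DoseDamagePoint(rtype, study_id, float(dose), float(dmg), comp)
                )
            study_id += 1
    return points


# ---------------------------------------------------------------------------
# CSV schemas (UTF-8, LF, decimal point; units embedded in headers)
# ---------------------------------------------------------------------------


def doe_to_frame(records: Sequence[DoERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "voltage_kV": [r.params.voltage for r in records],
            "frequency_kHz": [r.params.frequency for r in records],
            "flow_slm": [r.params.flow for r in records],
            "time_s": [r.params.time for r in records],
            "damage_pct": [r.damage for r in records],
        }
    )


def doe_from_frame(df: pd.DataFrame) -> list[DoERecord]:
    missing = set(DOE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"DoE table missing columns: {sorted(missing)}")
    return [
        DoERecord(
            ProcessParams(row.voltage_kV, row.frequency_kHz, row.flow_slm, row.time_s),
            float(row.damage_pct),
        )
        for row in df.itertuples(index=False)
    ]


def write_doe_csv(records: Sequence[DoERecord], path: str | Path) -> None:
    doe_to_frame(records).to_csv(path, index=False, lineterminator="\n")


def read_doe_csv(path: str | Path) -> list[DoERecord]:
    return doe_from_frame(pd.read_csv(path))


def db_to_frame(points: Sequence[DoseDamagePoint], include_provenance: bool = False) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "radiation_type": [p.radiation_type for p in points],
            "study_id": [p.study_id for p in points],
            "dose_Gy": [p.dose for p in points],
            "damage_pct": [p.damage for p in points],
        }
    )
    if include_provenance:
        df["component"] = [p.component for p in points]
    return df


def db_from_frame(df: pd.DataFrame) -> list[DoseDamagePoint]:
    missing = set(DB_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"dose-damage table missing columns: {sorted(missing)}")
    has_comp = "component" in df.columns
    return [
        DoseDamagePoint(
            row.radiation_type,
            int(row.study_id),
            float(row.dose_Gy),
            float(row.damage_pct),
            int(row.component) if has_comp and not pd.isna(row.component) else None,
        )
        for row in df.itertuples(index=False)
    ]


def write_db_csv(
    points: Sequence[DoseDamagePoint], path: str | Path, include_provenance: bool = False
) -> None:
    db_to_frame(points, include_provenance).to_csv(path, index=False, lineterminator="\n")


def read_db_csv(path: str | Path) -> list[DoseDamagePoint]:
    return db_from_frame(pd.read_csv(path))
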