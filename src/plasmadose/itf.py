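"""Irradiation-time finder: invert a damage predictor in time.

At fixed (voltage, frequency, flow) the predictor traces a damage-vs-time
curve; ``find_irradiation_time`` returns the smallest time at which that
curve meets a target damage level, by coarse grid bracketing followed by
bisection.  On a physically consistent (monotone) predictor the answer is
the unique crossing; residual non-monotonicity triggers a warning and the
smallest crossing is returned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ConsistencyViolationWarning, UnreachableTargetError

__all__ = ["ITFQuery", "InversionSettings", "find_irradiation_time"]


@dataclass(frozen=True)
class InversionSettings:
    """Numerical knobs of the inversion, shared by batch callers."""

    t_min: float = 0.5
    t_max: float = 120.0
    tolerance: float = 0.1    # % damage
    grid_points: int = 256
    time_resolution: float = 1e-3  # s

    def __post_init__(self) -> None:
        if not (0 <= self.t_min < self.t_max):
            raise ConfigurationError("need 0 <= t_min < t_max")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        if self.grid_points < 2:
            raise ConfigurationError("grid_points must be >= 2")


@dataclass(frozen=True)
class ITFQuery:
    """One inversion request: fixed plasma point, target damage, domain."""

    voltage: float
    frequency: float
    flow: float
    target_damage: float
    t_min: float = 0.5
    t_max: float = 120.0
    tolerance: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_damage <= 100.0):
            raise ConfigurationError("target_damage must be in [0, 100]")
        if not (0 <= self.t_min < self.t_max):
            raise ConfigurationError("need 0 <= t_min < t_max")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be > 0")
        for name in ("voltage", "frequency", "flow"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")


def _curve(predictor, query: ITFQuery, times: np.ndarray) -> np.ndarray:
    X = np.column_stack(
        [
            np.full_like(times, query.voltage),
            np.full_like(times, query.frequency),
            np.full_like(times, query.flow),
            times,
        ]
    )
    return np.asarray(predictor.predict(X), dtype=float).ravel()


def _point(predictor, query: ITFQuery, t: float) -> float:
    return float(
        np.asarray(
            predictor.predict(
                np.array([[query.voltage, query.frequency, query.flow, t]])
            )
        ).ravel()[0]
    )


def find_irradiation_time(
    predictor,
    query: ITFQuery,
    grid_points: int = 256,
    time_resolution: float = 1e-3,
) -> float:
    """Smallest t in [t_min, t_max] where the predicted damage meets the target.

    Raises :class:`UnreachableTargetError` (code ``below_range`` /
    ``above_range``) when the target lies outside the curve's range by
    more than the tolerance.  Warns when the curve decreases along the
    coarse grid but still returns the smallest crossing.
    """
    ts = np.linspace(query.t_min, query.t_max, grid_points)
    vals = _curve(predictor, query, ts)
    target = query.target_damage

    scale = max(1.0, np.abs(vals).max())
    if np.any(np.diff(vals) < -1e-9 * scale):
        warnings.warn(
            "predictor is not monotone in time on the inversion grid; "
            "returning the smallest crossing",
            ConsistencyViolationWarning,
        )

    g = vals - target
    if abs(g[0]) <= query.tolerance:
        return float(ts[0])

    # first sign change along the grid = smallest crossing
    sign_change = np.flatnonzero(g[:-1] * g[1:] <= 0)
    if sign_change.size:
        i = int(sign_change[0])
        lo, hi = float(ts[i]), float(ts[i + 1])
        g_lo = g[i]
        while hi - lo > time_resolution:
            mid = 0.5 * (lo + hi)
            g_mid = _point(predictor, query, mid) - target
            if g_mid == 0.0:
                return mid
            if (g_mid > 0) == (g_lo > 0):
                lo, g_lo = mid, g_mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    # no crossing; maybe a grid point already sits inside the tolerance band
    within = np.flatnonzero(np.abs(g) <= query.tolerance)
    if within.size:
        return float(ts[within[0]])

    if target < vals[0] - query.tolerance:
        raise UnreachableTargetError(
            "below_range",
            f"target {target}% is below the curve at t_min "
            f"(f(t_min) = {vals[0]:.4g}%)",
        )
    raise UnreachableTargetError(
        "above_range",
        f"target {target}% exceeds the curve over the domain "
        f"(f(t_max) = {vals[-1]:.4g}%)",
    )
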