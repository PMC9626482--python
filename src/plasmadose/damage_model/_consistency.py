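"""Monotonicity audit of fitted predictors."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..errors import ConfigurationError

__all__ = ["ViolationReport", "check_physical_consistency"]


@dataclass
class ViolationReport:
    """Every consecutive-time decrease found on the audit grid.

    ``locations`` holds (voltage, frequency, flow, t_lo, t_hi, drop) for
    each violating pair, where ``drop`` = f(t_lo) - f(t_hi) > 0.
    """

    count: int
    max_magnitude: float
    locations: list[tuple[float, float, float, float, float, float]] = field(
        default_factory=list
    )

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "max_magnitude": self.max_magnitude,
            "locations": [
                {
                    "voltage_kV": v,
                    "frequency_kHz": f,
                    "flow_slm": q,
                    "t_lo_s": tl,
                    "t_hi_s": th,
                    "drop_pct": d,
                }
                for v, f, q, tl, th, d in self.locations
            ],
        }


def check_physical_consistency(
    predictor,
    param_grid: Sequence[tuple[float, float, float]],
    time_grid: np.ndarray,
    atol: float = 0.0,
) -> ViolationReport:
    """Scan predicted damage over a time grid at each (V, f, Q) anchor.

    Deterministic for a fixed predictor and grids.  ``atol`` ignores drops
    at or below that magnitude (default: any strict decrease counts).
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size < 2:
        return ViolationReport(count=0, max_magnitude=0.0)
    if np.any(np.diff(t) < 0):
        raise ConfigurationError("time grid must be sorted ascending")
    predict = predictor.predict if hasattr(predictor, "predict") else predictor
    locations = []
    for v, f, q in param_grid:
        X = np.column_stack(
            [np.full_like(t, v), np.full_like(t, f), np.full_like(t, q), t]
        )
        pred = np.asarray(predict(X), dtype=float).ravel()
        drops = pred[:-1] - pred[1:]
        for i in np.flatnonzero(drops > atol):
            locations.append(
                (float(v), float(f), float(q), float(t[i]), float(t[i + 1]), float(drops[i]))
            )
    max_mag = max((loc[5] for loc in locations), default=0.0)
    return ViolationReport(count=len(locations), max_magnitude=max_mag, locations=locations)
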