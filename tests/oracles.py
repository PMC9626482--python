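"""Independent reference implementations used only to check the package."""

from __future__ import annotations

import numpy as np


class TimeCurvePredictor:
    """Wrap a scalar function of time as a (V, f, Q, t) predictor."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray(self.fn(X[:, 3]), dtype=float)


def dp_kmeans_wcss(values, k: int) -> float:
    """Exact optimal 1-D k-means WCSS by dynamic programming over sorted values."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    ps = np.concatenate([[0.0], np.cumsum(x)])
    ps2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i, j):  # contiguous block x[i:j]
        s, s2, m = ps[j] - ps[i], ps2[j] - ps2[i], j - i
        return s2 - s * s / m

    inf = float("inf")
    D = [[inf] * (n + 1) for _ in range(k + 1)]
    D[0][0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            D[kk][j] = min(D[kk - 1][i] + cost(i, j) for i in range(kk - 1, j))
    return D[k][n]


def dense_scan_inverse(curve_fn, target, t_min, t_max, n=100_000):
    """Grid-scan oracle: smallest grid time whose value crosses the target."""
    ts = np.linspace(t_min, t_max, n)
    vals = np.asarray(curve_fn(ts), dtype=float)
    g = vals - target
    crossings = np.flatnonzero(g[:-1] * g[1:] <= 0)
    if crossings.size == 0:
        return None
    return float(ts[crossings[0]])
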