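"""Physics-guided neural-network regressor.

A fully connected tanh network (default 3 hidden layers x 50 neurons)
trained with Adam on the mean-squared prediction error plus a physics
penalty: a hinge on every consecutive-time decrease of the predicted
damage over a collocation set of unlabeled operating points.  The penalty
is zero exactly when predictions are non-decreasing in time on that set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ..errors import ConfigurationError, InsufficientDataError, TrainingDivergedError
from ..synthetic_data import DoERecord

__all__ = [
    "CollocationSpec",
    "ModelConfig",
    "PGNNRegressor",
    "physical_loss",
    "make_collocation",
    "collocation_from_records",
    "train_pgnn",
]

# collocation set: sequence of ((voltage, frequency, flow), sorted time grid)
Collocation = Sequence[tuple[tuple[float, float, float], np.ndarray]]


@dataclass(frozen=True)
class CollocationSpec:
    """Density of the unlabeled monotonicity-audit grid used in training."""

    anchors: int = 32          # random (V, f, Q) anchor points (+ 8 box corners)
    times_per_anchor: int = 32

    def __post_init__(self) -> None:
        if self.anchors < 1 or self.times_per_anchor < 2:
            raise ConfigurationError("need >= 1 anchor and >= 2 times per anchor")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters for a damage predictor.

    ``grid`` optionally holds per-hyperparameter candidate lists for
    grid-search CV; keys override the scalar defaults here.
    """

    algorithm: str = "pgnn"
    hidden_layers: int = 3
    neurons_per_layer: int = 50
    phys_weight: float = 1000.0  # hinge is inactive when satisfied, so a
    epochs: int = 2000           # heavy weight costs no accuracy
    learning_rate: float = 5e-3
    collocation: CollocationSpec = field(default_factory=CollocationSpec)
    seed: int = 0
    early_stopping: bool = True
    patience: int = 100
    val_fraction: float = 0.1
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hidden_layers < 1 or self.neurons_per_layer < 1:
            raise ConfigurationError("need >= 1 hidden layer and >= 1 neuron")
        if self.phys_weight < 0:
            raise ConfigurationError("phys_weight must be >= 0")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")


def _resolve_predict(fn) -> Callable[[np.ndarray], np.ndarray]:
    if hasattr(fn, "predict"):
        return fn.predict
    if callable(fn):
        return fn
    raise TypeError("expected a predictor with .predict or a callable")


def _validate_collocation(collocation: Collocation) -> None:
    for _, times in collocation:
        t = np.asarray(times, dtype=float)
        if t.size >= 2 and np.any(np.diff(t) < 0):
            raise ConfigurationError("collocation time grid must be sorted ascending")


def physical_loss(predict_fn, collocation: Collocation) -> float:
    """Mean hinge penalty on consecutive-time prediction decreases.

    Returns ``mean(max(0, f(x, t_i) - f(x, t_{i+1})))`` over all
    consecutive time pairs of every anchor; 0.0 iff predictions are
    non-decreasing in time on the collocation set (and when there are no
    pairs at all).
    """
    _validate_collocation(collocation)
    predict = _resolve_predict(predict_fn)
    drops: list[np.ndarray] = []
    for (v, f, q), times in collocation:
        t = np.asarray(times, dtype=float)
        if t.size < 2:
            continue
        X = np.column_stack(
            [np.full_like(t, v), np.full_like(t, f), np.full_like(t, q), t]
        )
        pred = np.asarray(predict(X), dtype=float).ravel()
        drops.append(np.maximum(0.0, pred[:-1] - pred[1:]))
    if not drops:
        return 0.0
    return float(np.mean(np.concatenate(drops)))


def make_collocation(anchors: np.ndarray, times: np.ndarray) -> list:
    """Pair every (V, f, Q) anchor row with a shared sorted time grid."""
    t = np.sort(np.asarray(times, dtype=float))
    return [((float(a[0]), float(a[1]), float(a[2])), t.copy()) for a in np.atleast_2d(anchors)]


def _box_collocation(X: np.ndarray, spec: CollocationSpec, rng: np.random.Generator) -> list:
    lo, hi = X.min(axis=0), X.max(axis=0)
    anchors = rng.uniform(lo[:3], hi[:3], size=(spec.anchors, 3))
    # the 8 corners of the (V, f, Q) box are always anchored: saturated
    # plateaus at extreme settings are where soft monotonicity fails first
    corners = np.array(
        [[v, f, q] for v in (lo[0], hi[0]) for f in (lo[1], hi[1]) for q in (lo[2], hi[2])]
    )
    anchors = np.vstack([anchors, corners])
    t_hi = hi[3] if hi[3] > 0 else 1.0
    times = np.linspace(max(lo[3], 0.0), t_hi, spec.times_per_anchor)
    return make_collocation(anchors, times)


def collocation_from_records(
    records: Sequence[DoERecord], spec: CollocationSpec, seed: int = 0
) -> list:
    """Random anchors in the training feature box, plus its 8 corners."""
    X = np.array(
        [[r.params.voltage, r.params.frequency, r.params.flow, r.params.time] for r in records]
    )
    return _box_collocation(X, spec, np.random.default_rng(seed))


class PGNNRegressor:
    """Monotonicity-penalized MLP mapping (V, f, Q, t) to % damage.

    Inputs are z-scored and the target affinely rescaled using training
    statistics (stored on the fitted model); both loss terms are computed
    in % units.  Predictions are clipped to [0, 100] at the public
    boundary only, so training gradients are unaffected.
    """

    def __init__(
        self,
        hidden_layers: int = 3,
        neurons_per_layer: int = 50,
        phys_weight: float = 1000.0,
        epochs: int = 2000,
        learning_rate: float = 5e-3,
        seed: int = 0,
        early_stopping: bool = True,
        patience: int = 100,
        val_fraction: float = 0.1,
    ):
        self.hidden_layers = hidden_layers
        self.neurons_per_layer = neurons_per_layer
        self.phys_weight = phys_weight
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.early_stopping = early_stopping
        self.patience = patience
        self.val_fraction = val_fraction
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.training_log_: list[dict] = []
        self.collocation_: list | None = None

    # -- internals ---------------------------------------------------------

    def _init_net(self, rng: np.random.Generator) -> None:
        sizes = [4] + [self.neurons_per_layer] * self.hidden_layers + [1]
        self.weights_ = [
            rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))
            for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
        ]
        self.biases_ = [np.zeros(fan_out) for fan_out in sizes[1:]]

    def _forward(self, Xs: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        acts = [Xs]
        h = Xs
        for W, b in zip(self.weights_[:-1], self.biases_[:-1]):
            h = np.tanh(h @ W + b)
            acts.append(h)
        out = h @ self.weights_[-1] + self.biases_[-1]
        return acts, out.ravel()

    def _backward(self, acts: list[np.ndarray], d_out: np.ndarray) -> tuple[list, list]:
        gW = [None] * len(self.weights_)
        gb = [None] * len(self.biases_)
        delta = d_out[:, None]
        for li in range(len(self.weights_) - 1, -1, -1):
            gW[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
            if li > 0:
                delta = (delta @ self.weights_[li].T) * (1.0 - acts[li] ** 2)
        return gW, gb

    def _scaled_inputs(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.x_mean_) / self.x_sd_

    # -- public API --------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        collocation: Collocation | None = None,
    ) -> "PGNNRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] == 0:
            raise InsufficientDataError("empty training set")
        rng = np.random.default_rng(self.seed)

        self.x_mean_ = X.mean(axis=0)
        self.x_sd_ = X.std(axis=0)
        self.x_sd_[self.x_sd_ == 0] = 1.0
        self.y_mean_ = float(y.mean())
        self.y_sd_ = float(y.std()) or 1.0

        if collocation is None:
            collocation = _box_collocation(X, CollocationSpec(), rng)
        _validate_collocation(collocation)
        self.collocation_ = list(collocation)

        # flatten collocation anchor-major; pairs are consecutive rows per anchor
        xc_blocks, pair_slices, row0 = [], [], 0
        for (v, f, q), times in self.collocation_:
            t = np.asarray(times, dtype=float)
            xc_blocks.append(
                np.column_stack([np.full_like(t, v), np.full_like(t, f), np.full_like(t, q), t])
            )
            pair_slices.append((row0, row0 + t.size))
            row0 += t.size
        Xc = np.vstack(xc_blocks)
        n_pairs = sum(max(0, b - a - 1) for a, b in pair_slices)

        # held-out slice for early stopping
        if self.early_stopping and X.shape[0] >= 10 and self.val_fraction > 0:
            perm = rng.permutation(X.shape[0])
            n_val = max(1, int(round(self.val_fraction * X.shape[0])))
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
        else:
            val_idx, tr_idx = np.array([], dtype=int), np.arange(X.shape[0])

        Xs_tr, y_tr = self._scaled_inputs(X[tr_idx]), y[tr_idx]
        Xs_val, y_val = self._scaled_inputs(X[val_idx]), y[val_idx]
        Xs_c = self._scaled_inputs(Xc)
        n_tr = len(y_tr)

        self._init_net(rng)
        params = self.weights_ + self.biases_
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        b1, b2, eps = 0.9, 0.999, 1e-8

        best_val, best_state, stall = np.inf, None, 0
        self.training_log_ = []
        for epoch in range(1, self.epochs + 1):
            acts_tr, out_tr = self._forward(Xs_tr)
            pred_tr = self.y_mean_ + self.y_sd_ * out_tr
            resid = pred_tr - y_tr
            mse = float(np.mean(resid**2))

            acts_c, out_c = self._forward(Xs_c)
            pred_c = self.y_mean_ + self.y_sd_ * out_c
            g_pred_c = np.zeros_like(pred_c)
            phyloss = 0.0
            if n_pairs > 0:
                for a, b in pair_slices:
                    d = pred_c[a:b - 1] - pred_c[a + 1:b]
                    active = d > 0
                    phyloss += float(d[active].sum())
                    g_pred_c[a:b - 1][active] += 1.0
                    g_pred_c[a + 1:b][active] -= 1.0
                phyloss /= n_pairs
                g_pred_c /= n_pairs

            loss = mse + self.phys_weight * phyloss
            if not np.isfinite(loss):
                raise TrainingDivergedError(epoch)

            d_out_tr = (2.0 / n_tr) * resid * self.y_sd_
            gW, gb = self._backward(acts_tr, d_out_tr)
            if self.phys_weight > 0 and n_pairs > 0:
                d_out_c = self.phys_weight * g_pred_c * self.y_sd_
                gWc, gbc = self._backward(acts_c, d_out_c)
                gW = [a + b_ for a, b_ in zip(gW, gWc)]
                gb = [a + b_ for a, b_ in zip(gb, gbc)]

            grads = gW + gb
            t_ = epoch
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = b1 * m[i] + (1 - b1) * g
                v[i] = b2 * v[i] + (1 - b2) * g * g
                mhat = m[i] / (1 - b1**t_)
                vhat = v[i] / (1 - b2**t_)
                p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)

            entry = {"epoch": epoch, "mse": mse, "phyloss": phyloss, "loss": loss}
            if len(val_idx):
                _, out_val = self._forward(Xs_val)
                val_mse = float(np.mean((self.y_mean_ + self.y_sd_ * out_val - y_val) ** 2))
                entry["val_mse"] = val_mse
                # model selection respects the physics term too, so the
                # retained state is both accurate and monotone
                val_score = val_mse + self.phys_weight * phyloss
                if val_score < best_val - 1e-12:
                    best_val, stall = val_score, 0
                    best_state = ([w.copy() for w in self.weights_],
                                  [bb.copy() for bb in self.biases_])
                else:
                    stall += 1
                    if stall >= self.patience:
                        self.training_log_.append(entry)
                        break
            self.training_log_.append(entry)

        if best_state is not None:
            self.weights_, self.biases_ = best_state
        return self

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        """Unclipped predictions in % damage."""
        if self.weights_ is None:
            raise RuntimeError("model is not fitted")
        _, out = self._forward(self._scaled_inputs(X))
        return self.y_mean_ + self.y_sd_ * out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.clip(self.predict_raw(X), 0.0, 100.0)

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "format": "plasmadose-pgnn-v1",
            "hidden_layers": self.hidden_layers,
            "neurons_per_layer": self.neurons_per_layer,
            "phys_weight": self.phys_weight,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "x_mean": self.x_mean_.tolist(),
            "x_sd": self.x_sd_.tolist(),
            "y_mean": self.y_mean_,
            "y_sd": self.y_sd_,
            "weights": [w.tolist() for w in self.weights_],
            "biases": [b.tolist() for b in self.biases_],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PGNNRegressor":
        if d.get("format") != "plasmadose-pgnn-v1":
            raise ConfigurationError("unrecognized predictor format")
        model = cls(
            hidden_layers=d["hidden_layers"],
            neurons_per_layer=d["neurons_per_layer"],
            phys_weight=d["phys_weight"],
            epochs=d["epochs"],
            learning_rate=d["learning_rate"],
            seed=d["seed"],
        )
        model.x_mean_ = np.array(d["x_mean"])
        model.x_sd_ = np.array(d["x_sd"])
        model.y_mean_ = float(d["y_mean"])
        model.y_sd_ = float(d["y_sd"])
        model.weights_ = [np.array(w) for w in d["weights"]]
        model.biases_ = [np.array(b) for b in d["biases"]]
        return model


def train_pgnn(records: Sequence[DoERecord], config: ModelConfig) -> PGNNRegressor:
    """Fit the physics-guided network on DoE records."""
    if not records:
        raise InsufficientDataError("no training records")
    X = np.array(
        [[r.params.voltage, r.params.frequency, r.params.flow, r.params.time] for r in records]
    )
    y = np.array([r.damage for r in records])
    model = PGNNRegressor(
        hidden_layers=config.hidden_layers,
        neurons_per_layer=config.neurons_per_layer,
        phys_weight=config.phys_weight,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        seed=config.seed,
        early_stopping=config.early_stopping,
        patience=config.patience,
        val_fraction=config.val_fraction,
    )
    collocation = collocation_from_records(records, config.collocation, seed=config.seed)
    return model.fit(X, y, collocation=collocation)
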