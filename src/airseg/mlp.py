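"""Fixed-architecture perceptron regression trained by quasi-Newton descent.

The network is inputs → ``hidden_units`` logistic units → 1 logistic output.
Training minimizes the sum-of-squares loss on the training split with BFGS,
capped at ``max_epochs`` iterations (one epoch = one full-batch BFGS
iteration), from zero-mean Gaussian initial weights.  Because the output unit
is logistic, inputs are min–max scaled to [0, 1] and the target is mapped
into a sub-interval of (0, 1) (default (0.1, 0.9)) to keep it away from
saturation; predictions are mapped back to concentration units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from .data_prep import TRAIN, VALID, CaseTable, SplitAssignment
from .errors import DegenerateSegmentError, SchemaError

__all__ = [
    "ScalingParams",
    "TrainConfig",
    "MLPModel",
    "fit_mlp",
    "fit_best_of_restarts",
    "predict",
    "derive_restart_seeds",
]


@dataclass(frozen=True)
class ScalingParams:
    """Affine min–max scaling fitted on the training split.

    Features map to [0, 1]; the target maps to the squash range
    (``squash_lo``, ``squash_hi``) inside (0, 1).  Values outside the training
    range are extrapolated through the same affine map.
    """

    feature_names: tuple[str, ...]
    feature_min: np.ndarray
    feature_max: np.ndarray
    target_min: float
    target_max: float
    squash_lo: float = 0.1
    squash_hi: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.squash_lo < self.squash_hi < 1.0):
            raise ValueError("squash range must satisfy 0 < lo < hi < 1")
        if self.target_max <= self.target_min:
            raise DegenerateSegmentError("target has zero range")

    def _feature_span(self) -> np.ndarray:
        span = self.feature_max - self.feature_min
        # constant feature columns carry no information; map them to 0
        return np.where(span > 0, span, 1.0)

    def scale_X(self, X: np.ndarray) -> np.ndarray:
        return (X - self.feature_min) / self._feature_span()

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        frac = (y - self.target_min) / (self.target_max - self.target_min)
        return self.squash_lo + frac * (self.squash_hi - self.squash_lo)

    def unscale_y(self, y_scaled: np.ndarray) -> np.ndarray:
        frac = (y_scaled - self.squash_lo) / (self.squash_hi - self.squash_lo)
        return self.target_min + frac * (self.target_max - self.target_min)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the reference protocol)."""

    hidden_units: int = 10
    max_epochs: int = 300
    restarts: int = 5
    init_sigma: float = 0.5
    seed: int = 0
    gtol: float = 1e-6

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.init_sigma <= 0:
            raise ValueError("init_sigma must be positive")


@dataclass
class MLPModel:
    """A trained one-hidden-layer perceptron plus its scaling parameters."""

    w1: np.ndarray  # (n_features, hidden)
    b1: np.ndarray  # (hidden,)
    w2: np.ndarray  # (hidden,)
    b2: float
    scaling: ScalingParams
    meta: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.scaling.feature_names

    @property
    def hidden_units(self) -> int:
        return self.w1.shape[1]

    def predict(self, cases) -> np.ndarray:
        return predict(self, cases)

    def to_dict(self) -> dict:
        return {
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": float(self.b2),
            "scaling": {
                "feature_names": list(self.scaling.feature_names),
                "feature_min": self.scaling.feature_min.tolist(),
                "feature_max": self.scaling.feature_max.tolist(),
                "target_min": self.scaling.target_min,
                "target_max": self.scaling.target_max,
                "squash_lo": self.scaling.squash_lo,
                "squash_hi": self.scaling.squash_hi,
            },
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        s = d["scaling"]
        scaling = ScalingParams(
            feature_names=tuple(s["feature_names"]),
            feature_min=np.asarray(s["feature_min"], dtype=float),
            feature_max=np.asarray(s["feature_max"], dtype=float),
            target_min=float(s["target_min"]),
            target_max=float(s["target_max"]),
            squash_lo=float(s["squash_lo"]),
            squash_hi=float(s["squash_hi"]),
        )
        return cls(
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            scaling=scaling,
            meta=dict(d.get("meta", {})),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "MLPModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _n_params(d: int, h: int) -> int:
    return d * h + h + h + 1


def _unpack(theta: np.ndarray, d: int, h: int):
    w1 = theta[: d * h].reshape(d, h)
    b1 = theta[d * h : d * h + h]
    w2 = theta[d * h + h : d * h + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _forward(theta: np.ndarray, X: np.ndarray, h: int):
    d = X.shape[1]
    w1, b1, w2, b2 = _unpack(theta, d, h)
    a1 = expit(X @ w1 + b1)
    out = expit(a1 @ w2 + b2)
    return a1, out


def sos_and_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray, h: int):
    """Sum-of-squares loss Σ(pred − y)² and its analytic gradient."""
    d = X.shape[1]
    w1, b1, w2, b2 = _unpack(theta, d, h)
    a1, out = _forward(theta, X, h)
    r = out - y
    loss = float(r @ r)
    dout = 2.0 * r * out * (1.0 - out)
    gw2 = a1.T @ dout
    gb2 = float(np.sum(dout))
    dz1 = np.outer(dout, w2) * a1 * (1.0 - a1)
    gw1 = X.T @ dz1
    gb1 = dz1.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2, [gb2]])
    return loss, grad


def sos(theta: np.ndarray, X: np.ndarray, y: np.ndarray, h: int) -> float:
    _, out = _forward(theta, X, h)
    r = out - y
    return float(r @ r)


def derive_restart_seeds(master_seed: int, restarts: int) -> list[int]:
    """Deterministic per-restart seeds derived from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) for s in ss.generate_state(restarts)]


def fit_mlp(
    table: CaseTable,
    split: SplitAssignment,
    cfg: TrainConfig,
    restart_seed: int,
) -> MLPModel:
    """Train one perceptron from a single Gaussian initialization.

    Deterministic given (table, split, cfg, restart_seed).  Raises
    :class:`DegenerateSegmentError` when the training-split target has no
    variability.
    """
    train_mask = split.mask(TRAIN)
    X_train = table.X[train_mask]
    y_train = table.y[train_mask]
    if np.ptp(y_train) == 0:
        raise DegenerateSegmentError(
            f"target {table.target!r} constant on training split"
        )
    scaling = ScalingParams(
        feature_names=table.predictors,
        feature_min=X_train.min(axis=0),
        feature_max=X_train.max(axis=0),
        target_min=float(y_train.min()),
        target_max=float(y_train.max()),
    )
    Xs = scaling.scale_X(X_train)
    ys = scaling.scale_y(y_train)

    h = cfg.hidden_units
    rng = np.random.default_rng(restart_seed)
    theta0 = rng.normal(0.0, cfg.init_sigma, size=_n_params(Xs.shape[1], h))
    loss0 = sos(theta0, Xs, ys, h)

    res = minimize(
        sos_and_grad,
        theta0,
        args=(Xs, ys, h),
        jac=True,
        method="BFGS",
        options={"maxiter": cfg.max_epochs, "gtol": cfg.gtol},
    )
    theta = res.x
    train_sos = float(res.fun)
    if not np.isfinite(train_sos) or not np.all(np.isfinite(theta)):
        raise ArithmeticError("non-finite loss or weights after training")
    assert res.nit <= cfg.max_epochs
    assert train_sos <= loss0 + 1e-12

    valid_mask = split.mask(VALID)
    Xv = scaling.scale_X(table.X[valid_mask])
    yv = scaling.scale_y(table.y[valid_mask])
    valid_sos = sos(theta, Xv, yv, h) if len(yv) else float("nan")

    w1, b1, w2, b2 = _unpack(theta, Xs.shape[1], h)
    return MLPModel(
        w1=w1.copy(),
        b1=b1.copy(),
        w2=w2.copy(),
        b2=float(b2),
        scaling=scaling,
        meta={
            "train_sos": train_sos,
            "valid_sos": valid_sos,
            "epochs_used": int(res.nit),
            "restart_seed": int(restart_seed),
            "n_train": int(len(y_train)),
            "target": table.target,
        },
    )


def fit_best_of_restarts(
    table: CaseTable, split: SplitAssignment, cfg: TrainConfig
) -> MLPModel:
    """Train ``cfg.restarts`` networks from distinct seeds, keep the best.

    The winner is the model with the lowest validation SOS (ties broken by
    lower restart index); per-restart SOS values are recorded in ``meta``.
    """
    seeds = derive_restart_seeds(cfg.seed, cfg.restarts)
    models: list[MLPModel] = []
    failures: list[str] = []
    for i, s in enumerate(seeds):
        try:
            models.append(fit_mlp(table, split, cfg, restart_seed=s))
        except DegenerateSegmentError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported to caller
            failures.append(f"restart {i} (seed {s}): {exc}")
    if not models:
        raise RuntimeError("all restarts failed: " + "; ".join(failures))
    valid_sos = [m.meta["valid_sos"] for m in models]
    best = int(np.argmin(valid_sos))  # argmin keeps the first on ties
    model = models[best]
    model.meta["restart_valid_sos"] = [float(v) for v in valid_sos]
    model.meta["selected_restart"] = best
    if failures:
        model.meta["failed_restarts"] = failures
    return model


def predict(model: MLPModel, cases) -> np.ndarray:
    """Forward pass followed by unscaling back to concentration units.

    ``cases`` may be a :class:`CaseTable`, a DataFrame containing the model's
    feature columns, or a raw array already in training-column order.
    """
    if isinstance(cases, CaseTable):
        frame = cases.frame
    elif isinstance(cases, pd.DataFrame):
        frame = cases
    else:
        X = np.asarray(cases, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(model.feature_names):
            raise SchemaError(
                f"expected {len(model.feature_names)} feature columns"
            )
        return _predict_array(model, X)
    missing = set(model.feature_names) - set(frame.columns)
    if missing:
        raise SchemaError(f"cases lack model feature(s): {sorted(missing)}")
    X = frame[list(model.feature_names)].to_numpy(dtype=float)
    return _predict_array(model, X)


def _predict_array(model: MLPModel, X: np.ndarray) -> np.ndarray:
    Xs = model.scaling.scale_X(X)
    a1 = expit(Xs @ model.w1 + model.b1)
    out = expit(a1 @ model.w2 + model.b2)
    return model.scaling.unscale_y(out)
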