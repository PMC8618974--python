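"""Small MLP regressor with standardization and the train/test reversal protocol.

The network is deliberately tiny (one hidden layer, four units by default)
to match the study design it re-implements: a functional approximator over
a handful of selected tabular inputs.  Training is delegated to
scikit-learn's :class:`~sklearn.neural_network.MLPRegressor` with an
L-BFGS solver (deterministic per seed on small problems); scaling is owned
here so the reversal protocol can guarantee fold isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

from .errors import ConfigurationError, DataError

__all__ = [
    "MLPSpec",
    "ScalingParams",
    "fit_scaler",
    "apply_scaler",
    "invert_scaler",
    "TrainedMLP",
    "train_mlp",
    "reversal_blind_predict",
]


@dataclass(frozen=True)
class MLPSpec:
    hidden_units: int = 4
    activation: str = "tanh"  # tanh | logistic
    max_epochs: int = 400
    learning_rate: float = 1e-3  # used only by first-order solvers
    early_stop_patience: int = 10
    seed: int = 0
    solver: str = "lbfgs"

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ConfigurationError("hidden_units must be >= 1")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.activation not in ("tanh", "logistic"):
            raise ConfigurationError(f"unsupported activation {self.activation!r}")


@dataclass(frozen=True)
class ScalingParams:
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "scale", np.asarray(self.scale, dtype=float))


def fit_scaler(data, column_names=None) -> ScalingParams:
    """Per-column z-standardization parameters (ddof=0 SD)."""
    arr = np.atleast_2d(np.asarray(data, dtype=float))
    if arr.shape[0] < 2:
        raise ConfigurationError("scaling requires at least two rows")
    center = arr.mean(axis=0)
    scale = arr.std(axis=0)
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        names = (
            [column_names[i] for i in bad]
            if column_names is not None
            else [f"column {i}" for i in bad]
        )
        raise ConfigurationError(f"constant column(s) cannot be scaled: {names}")
    return ScalingParams(center=center, scale=scale)


def apply_scaler(data, params: ScalingParams) -> np.ndarray:
    return (np.asarray(data, dtype=float) - params.center) / params.scale


def invert_scaler(scaled, params: ScalingParams) -> np.ndarray:
    return np.asarray(scaled, dtype=float) * params.scale + params.center


@dataclass
class TrainedMLP:
    spec: MLPSpec
    x_scaling: ScalingParams
    y_scaling: ScalingParams
    estimator: MLPRegressor = field(repr=False)
    feature_names: Optional[list[str]] = None

    def predict(self, X) -> np.ndarray:
        Xs = apply_scaler(np.atleast_2d(np.asarray(X, dtype=float)), self.x_scaling)
        ys = self.estimator.predict(Xs)
        return invert_scaler(ys, self.y_scaling).ravel()


def train_mlp(X, y, spec: MLPSpec, feature_names=None) -> TrainedMLP:
    """Fit the one-hidden-layer MLP on standardized inputs/target.

    Deterministic for a fixed spec seed.  Inputs with NaNs are rejected;
    constant columns must be filtered upstream.
    """
    # contiguity pinned so training is bit-reproducible regardless of how
    # the caller sliced the arrays (layout changes BLAS summation order)
    X = np.ascontiguousarray(np.atleast_2d(np.asarray(X, dtype=float)))
    y = np.ascontiguousarray(np.asarray(y, dtype=float).ravel())
    if X.shape[0] != y.shape[0]:
        raise DataError("X and y must have the same number of rows")
    if X.shape[0] < 10:
        raise DataError("training requires at least 10 records")
    if np.isnan(X).any() or np.isnan(y).any():
        raise DataError("NaN values in training data")
    x_scaling = fit_scaler(X, feature_names)
    y_scaling = fit_scaler(y.reshape(-1, 1))
    Xs = apply_scaler(X, x_scaling)
    ys = apply_scaler(y.reshape(-1, 1), y_scaling).ravel()
    est = MLPRegressor(
        hidden_layer_sizes=(spec.hidden_units,),
        activation=spec.activation,
        solver=spec.solver,
        max_iter=spec.max_epochs,
        learning_rate_init=spec.learning_rate,
        n_iter_no_change=spec.early_stop_patience,
        random_state=spec.seed,
        tol=1e-8,
    )
    with warnings.catch_warnings():
        # small max_iter budgets during GA fitness scans hit ConvergenceWarning
        warnings.simplefilter("ignore")
        est.fit(Xs, ys)
    return TrainedMLP(
        spec=spec,
        x_scaling=x_scaling,
        y_scaling=y_scaling,
        estimator=est,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def reversal_blind_predict(X, y, split_assignment, spec: MLPSpec) -> pd.DataFrame:
    """One blind prediction per record via the reversal protocol.

    ``split_assignment`` is a boolean vector (True = half A).  A model (and
    its scalers) fitted on half A predicts half B and vice versa, so no
    record is ever predicted by a model that saw it.  Returns a frame with
    columns ``predicted_ree_kcal_day`` and ``fold`` (``A->B``/``B->A``)
    indexed like the input rows.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    split = np.asarray(split_assignment, dtype=bool).ravel()
    if split.shape[0] != X.shape[0]:
        raise ConfigurationError("split_assignment must cover every record")
    if split.all() or (~split).all():
        raise ConfigurationError("both split halves must be nonempty")
    pred = np.empty_like(y)
    fold = np.empty(y.shape[0], dtype=object)
    for train_mask, label in ((split, "A->B"), (~split, "B->A")):
        # indicator columns can be constant within one half; they carry no
        # information for that fold and are dropped fold-locally
        usable = X[train_mask].std(axis=0) > 0
        if not usable.any():
            raise DataError("all features constant within a training half")
        model = train_mlp(X[train_mask][:, usable], y[train_mask], spec)
        test_mask = ~train_mask
        pred[test_mask] = model.predict(X[test_mask][:, usable])
        fold[test_mask] = label
    return pd.DataFrame({"predicted_ree_kcal_day": pred, "fold": fold})
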