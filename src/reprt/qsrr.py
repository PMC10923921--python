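"""Descriptor-based retention prediction (QSRR).

A quantitative structure-retention relationship predicts RT on a specific CM
from precomputed 2-D molecular descriptors.  The default regressor is a
single-hidden-layer perceptron (10 tanh units) with L2 regularization —
optionally selected automatically on an internal validation split — but any
tabular regressor honoring ``fit(X, y)`` / ``predict(X)`` with a seed can be
plugged in.  Descriptor computation is out of scope: the module consumes a
feature table whose first column is ``molecule_id`` and whose remaining
columns are named descriptors.

Preprocessing: zero-variance descriptors are dropped (logged), features and
targets are standardized to zero mean / unit variance, and predictions are
de-standardized back to minutes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor

__all__ = ["QSRRModel", "split_train_validation", "fit_qsrr", "predict_qsrr"]

logger = logging.getLogger(__name__)

#: L2 strengths scanned when reg_strength="auto"
AUTO_ALPHA_GRID = (1e-4, 1e-3, 1e-2, 1e-1, 1.0, 3.0, 10.0)

#: minimum training molecules for a meaningful fit
MIN_TRAIN = 50


def split_train_validation(
    molecule_ids,
    holdout_ids,
    fraction: float = 0.75,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Random train/validation split with a forced holdout.

    ``holdout_ids`` (e.g. molecules overlapping an external RT database) are
    excluded from training eligibility and always land in the validation
    set.  Of the remaining molecules, ``floor(fraction * n)`` are drawn for
    training; the rest join the validation set.  Deterministic given seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    ids = [str(m) for m in molecule_ids]
    holdout = {str(m) for m in holdout_ids}
    eligible = sorted(m for m in ids if m not in holdout)
    n_train = math.floor(fraction * len(eligible))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(eligible))
    train = sorted(eligible[i] for i in perm[:n_train])
    validation = sorted(set(ids) - set(train))
    return train, validation


@dataclass
class QSRRModel:
    """Fitted structure->RT regressor with its preprocessing constants."""

    feature_names: tuple[str, ...]
    hidden_units: int
    reg_strength: float
    seed: int
    x_mean: np.ndarray = field(repr=False)
    x_sd: np.ndarray = field(repr=False)
    y_mean: float = 0.0
    y_sd: float = 1.0
    regressor: object = field(default=None, repr=False)
    constant_prediction: float | None = None  # set when the target is constant

    @property
    def input_dim(self) -> int:
        return len(self.feature_names)


def _feature_frame(features: pd.DataFrame) -> pd.DataFrame:
    """Accept either molecule_id-indexed or molecule_id-column layouts."""
    if "molecule_id" in features.columns:
        features = features.set_index("molecule_id")
    return features


def _fit_one(Xz, yz, hidden_units, alpha, seed) -> MLPRegressor:
    reg = MLPRegressor(
        hidden_layer_sizes=(hidden_units,),
        activation="tanh",
        solver="lbfgs",
        alpha=alpha,
        max_iter=3000,
        random_state=seed,
    )
    reg.fit(Xz, yz)
    return reg


def fit_qsrr(
    features: pd.DataFrame,
    rts,
    hidden_units: int = 10,
    reg_strength: float | str = "auto",
    seed: int = 0,
    regressor_factory=None,
) -> QSRRModel:
    """Train the QSRR regressor on descriptor rows aligned with RTs.

    With ``reg_strength="auto"`` the L2 strength is chosen by an internal
    75/25 validation split over a small log grid.  Supplying
    ``regressor_factory(seed) -> estimator`` swaps in any other tabular
    regressor (the estimator sees standardized inputs/targets).
    """
    features = _feature_frame(features)
    y = np.asarray(rts, dtype=float)
    if len(features) != y.size:
        raise ValueError("fit_qsrr: features and rts are misaligned")
    if y.size < MIN_TRAIN:
        raise ValueError(f"fit_qsrr: need >= {MIN_TRAIN} training molecules")
    if features.isna().any().any():
        raise ValueError("fit_qsrr: NaN in feature matrix; impute or drop upstream")

    sd = features.std(axis=0, ddof=0)
    constant_cols = list(sd.index[sd == 0.0])
    if constant_cols:
        logger.info("dropping %d zero-variance descriptors: %s",
                    len(constant_cols), constant_cols[:10])
        features = features.drop(columns=constant_cols)
        sd = sd.drop(constant_cols)

    X = features.to_numpy(dtype=float)
    x_mean = X.mean(axis=0)
    x_sd = np.where(sd.to_numpy() > 0, sd.to_numpy(), 1.0)
    Xz = (X - x_mean) / x_sd

    y_mean, y_sd = float(y.mean()), float(y.std())
    model = QSRRModel(
        feature_names=tuple(features.columns),
        hidden_units=hidden_units,
        reg_strength=0.0,
        seed=seed,
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=max(y_sd, 1e-12),
    )
    if y_sd < 1e-12:  # constant target: nothing to learn
        model.constant_prediction = y_mean
        return model
    yz = (y - y_mean) / y_sd

    if regressor_factory is not None:
        reg = regressor_factory(seed)
        reg.fit(Xz, yz)
        model.regressor = reg
        return model

    if reg_strength == "auto":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(y.size)
        n_tr = math.floor(0.75 * y.size)
        tr, va = perm[:n_tr], perm[n_tr:]
        best = None
        for alpha in AUTO_ALPHA_GRID:
            reg = _fit_one(Xz[tr], yz[tr], hidden_units, alpha, seed)
            rmse = float(np.sqrt(np.mean((reg.predict(Xz[va]) - yz[va]) ** 2)))
            if best is None or rmse < best[0]:
                best = (rmse, alpha)
        alpha = best[1]
        logger.info("auto-selected L2 strength %.1e (val RMSE %.4f, z-units)",
                    alpha, best[0])
    else:
        alpha = float(reg_strength)

    model.reg_strength = alpha
    model.regressor = _fit_one(Xz, yz, hidden_units, alpha, seed)
    return model


def predict_qsrr(model: QSRRModel, features: pd.DataFrame) -> np.ndarray:
    """Predict RTs (minutes) for descriptor rows matching the training schema.

    Columns are aligned by name, so column order is irrelevant; extra
    columns are ignored and missing ones raise with their names.
    """
    features = _feature_frame(features)
    missing = [c for c in model.feature_names if c not in features.columns]
    if missing:
        raise ValueError(f"predict_qsrr: missing features {missing[:10]}")
    X = features.loc[:, list(model.feature_names)].to_numpy(dtype=float)
    if model.constant_prediction is not None:
        return np.full(X.shape[0], model.constant_prediction)
    Xz = (X - model.x_mean) / model.x_sd
    yz = np.asarray(model.regressor.predict(Xz), dtype=float)
    return yz * model.y_sd + model.y_mean
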