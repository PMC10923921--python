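"""Gaussian-process projection of retention times between two CMs.

Given paired calibrant retention times (x in the source CM, y in the target
CM), a 1-D GP regression with a constant mean, a rational-quadratic (RQ)
kernel and a fitted white-noise term maps any RT measured (or predicted) on
the source method onto the target method:

    k(x, x') = sigma_f^2 * (1 + (x - x')^2 / (2 alpha l^2))^(-alpha)

The RQ kernel is a scale mixture of squared-exponential kernels, which suits
gradient elution: RT relations between methods are smooth but mix short- and
long-range structure (dead-time plateau, steep mid-gradient, late plateau).
Hyperparameters maximize the log marginal likelihood via a quasi-Newton
(L-BFGS) optimizer with seeded random restarts.  Inputs and targets are
standardized before fitting; the constant mean is the training-target mean.

The heavy lifting is delegated to scikit-learn's GaussianProcessRegressor;
this module owns the model contract, standardization and serialization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import (
    ConstantKernel,
    RationalQuadratic,
    WhiteKernel,
)

__all__ = ["rq_kernel", "ProjectionModel", "ProjectionResult", "fit_projection", "project"]

#: lower bound on the fitted noise variance (standardized units); calibrant
#: RTs are noisy measurements, so exact interpolation is deliberately avoided
NOISE_FLOOR = 1e-6

#: minimum paired calibrants for a stable fit
MIN_POINTS = 5


def rq_kernel(x, x2, signal_var: float, length_scale: float, alpha: float):
    """Rational-quadratic covariance between scalar inputs (elementwise).

    ``signal_var`` is sigma_f^2 (covariance at zero distance), ``length_scale``
    the characteristic distance, ``alpha`` the scale-mixture shape; as
    alpha -> inf the RQ kernel approaches the squared exponential.
    """
    if signal_var <= 0 or length_scale <= 0 or alpha <= 0:
        raise ValueError("rq_kernel: hyperparameters must be positive")
    d2 = (np.asarray(x, dtype=float) - np.asarray(x2, dtype=float)) ** 2
    return signal_var * (1.0 + d2 / (2.0 * alpha * length_scale**2)) ** (-alpha)


@dataclass(frozen=True)
class ProjectionResult:
    """Posterior prediction in minutes, with extrapolation flags."""

    mean: np.ndarray
    sd: np.ndarray
    extrapolated: np.ndarray  # True where x_new is outside the training range


@dataclass
class ProjectionModel:
    """Fitted GP mapping RTs from ``source_cm`` to ``target_cm``.

    Hyperparameters are stored in standardized units (the scale on which
    they were optimized); ``standardization`` holds the affine constants
    needed to move between minutes and the fitting scale.  ``mean_const`` is
    the constant GP mean in minutes (the training-target mean).
    """

    source_cm: str
    target_cm: str
    mean_const: float
    rq_signal_var: float
    rq_length_scale: float
    rq_alpha: float
    noise_var: float
    train_x: np.ndarray
    train_y: np.ndarray
    standardization: tuple[float, float, float, float]  # x_mean, x_sd, y_mean, y_sd
    log_marginal_likelihood: float
    _gpr: GaussianProcessRegressor | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if min(self.rq_signal_var, self.rq_length_scale, self.rq_alpha) <= 0:
            raise ValueError("ProjectionModel: RQ hyperparameters must be positive")
        if self.noise_var < NOISE_FLOOR:
            raise ValueError(f"ProjectionModel: noise_var below floor {NOISE_FLOOR}")
        if len(self.train_x) != len(self.train_y) or len(self.train_x) < MIN_POINTS:
            raise ValueError(
                f"ProjectionModel: need >= {MIN_POINTS} paired training points"
            )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kernel": "constant_mean+rational_quadratic+white_noise",
            "source_cm": self.source_cm,
            "target_cm": self.target_cm,
            "mean_const": self.mean_const,
            "rq_signal_var": self.rq_signal_var,
            "rq_length_scale": self.rq_length_scale,
            "rq_alpha": self.rq_alpha,
            "noise_var": self.noise_var,
            "train_x": list(map(float, self.train_x)),
            "train_y": list(map(float, self.train_y)),
            "standardization": list(self.standardization),
            "log_marginal_likelihood": self.log_marginal_likelihood,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProjectionModel":
        return cls(
            source_cm=d["source_cm"],
            target_cm=d["target_cm"],
            mean_const=float(d["mean_const"]),
            rq_signal_var=float(d["rq_signal_var"]),
            rq_length_scale=float(d["rq_length_scale"]),
            rq_alpha=float(d["rq_alpha"]),
            noise_var=float(d["noise_var"]),
            train_x=np.asarray(d["train_x"], dtype=float),
            train_y=np.asarray(d["train_y"], dtype=float),
            standardization=tuple(float(v) for v in d["standardization"]),
            log_marginal_likelihood=float(d["log_marginal_likelihood"]),
        )

    # -- internal GP reconstruction ----------------------------------------

    def _ensure_gpr(self) -> GaussianProcessRegressor:
        if self._gpr is None:
            x_mean, x_sd, y_mean, y_sd = self.standardization
            kernel = ConstantKernel(self.rq_signal_var, "fixed") * RationalQuadratic(
                length_scale=self.rq_length_scale,
                alpha=self.rq_alpha,
                length_scale_bounds="fixed",
                alpha_bounds="fixed",
            ) + WhiteKernel(self.noise_var, "fixed")
            gpr = GaussianProcessRegressor(kernel=kernel, optimizer=None)
            xz = (self.train_x - x_mean) / x_sd
            yz = (self.train_y - y_mean) / y_sd
            gpr.fit(xz.reshape(-1, 1), yz)
            self._gpr = gpr
        return self._gpr


def _standardize_constants(v: np.ndarray) -> tuple[float, float]:
    mean = float(v.mean())
    sd = float(v.std())
    return mean, (sd if sd > 1e-12 else 1.0)


def fit_projection(
    x,
    y,
    source_cm: str = "",
    target_cm: str = "",
    seed: int = 0,
    n_restarts: int = 5,
) -> ProjectionModel:
    """Fit the GP projection model on paired calibrant RTs (minutes).

    Hyperparameters (RQ signal variance, length scale, shape, and the noise
    variance) are optimized by L-BFGS on the log marginal likelihood from
    ``n_restarts`` seeded log-uniform restarts; the best restart is kept.
    Duplicate x with inconsistent y is absorbed by the noise term.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fit_projection: x and y must be 1-D of equal length")
    if x.size < MIN_POINTS:
        raise ValueError(f"fit_projection: need >= {MIN_POINTS} calibrant pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("fit_projection: non-finite RT values")
    if not (np.all(x > 0) and np.all(y > 0)):
        raise ValueError("fit_projection: RTs must be positive")

    x_mean, x_sd = _standardize_constants(x)
    y_mean, y_sd = _standardize_constants(y)
    xz = ((x - x_mean) / x_sd).reshape(-1, 1)
    yz = (y - y_mean) / y_sd

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RationalQuadratic(
        length_scale=1.0,
        alpha=1.0,
        length_scale_bounds=(1e-2, 1e3),
        alpha_bounds=(1e-3, 1e4),
    ) + WhiteKernel(1e-2, (NOISE_FLOOR, 1e1))
    gpr = GaussianProcessRegressor(
        kernel=kernel,
        n_restarts_optimizer=n_restarts,
        random_state=seed,
        normalize_y=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gpr.fit(xz, yz)

    k = gpr.kernel_
    signal_var = float(k.k1.k1.constant_value)
    length_scale = float(k.k1.k2.length_scale)
    alpha = float(k.k1.k2.alpha)
    noise_var = max(float(k.k2.noise_level), NOISE_FLOOR)

    model = ProjectionModel(
        source_cm=source_cm,
        target_cm=target_cm,
        mean_const=y_mean,
        rq_signal_var=signal_var,
        rq_length_scale=length_scale,
        rq_alpha=alpha,
        noise_var=noise_var,
        train_x=x.copy(),
        train_y=y.copy(),
        standardization=(x_mean, x_sd, y_mean, y_sd),
        log_marginal_likelihood=float(gpr.log_marginal_likelihood_value_),
    )
    model._gpr = gpr
    return model


def project(model: ProjectionModel, x_new) -> ProjectionResult:
    """GP posterior mean and sd (minutes) at new source-CM RTs.

    Predictions outside the training RT range are allowed but flagged via
    ``extrapolated`` — the GP reverts to its constant mean far from data, so
    extrapolated values deserve scrutiny.
    """
    if not isinstance(model, ProjectionModel):
        raise TypeError("project: expected a fitted ProjectionModel")
    x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
    gpr = model._ensure_gpr()
    x_mean, x_sd, y_mean, y_sd = model.standardization
    xz = ((x_new - x_mean) / x_sd).reshape(-1, 1)
    mean_z, sd_z = gpr.predict(xz, return_std=True)
    lo, hi = model.train_x.min(), model.train_x.max()
    return ProjectionResult(
        mean=mean_z * y_sd + y_mean,
        sd=sd_z * y_sd,
        extrapolated=(x_new < lo) | (x_new > hi),
    )
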