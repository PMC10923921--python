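"""Elution-time-relative error metrics and correlation diagnostics.

Absolute RT errors in minutes are not comparable between a 10-minute and a
100-minute gradient, so errors are expressed as a percentage of the *elution
time* — the maximum calibrant retention time observed in the output method
(OCM).  The three headline statistics are

* ``RMSE_Ret`` — root-mean-square error as % of elution time,
* ``MedE_Ret`` — median absolute error as % of elution time,
* ``ME_Ret``   — mean signed error (bias) as % of elution time.

``r2`` throughout this package is the squared Pearson correlation
coefficient, not the coefficient of determination of any fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

__all__ = ["EvalMetrics", "elution_time", "error_ret", "summarize", "r_squared"]


@dataclass(frozen=True)
class EvalMetrics:
    """Summary of projection errors for one (ICM, OCM) comparison."""

    elution_time: float  # minutes
    rmse_ret: float  # % of elution time
    mede_ret: float  # % of elution time
    me_ret: float  # % of elution time, signed (bias) by default
    mae_min: float  # minutes
    rmse_min: float  # minutes
    r2: float  # squared Pearson correlation; NaN if undefined
    n: int

    def to_row(self, **keys) -> dict:
        """Flatten to a CSV-ready dict, prefixed with grouping keys
        (e.g. icm, reicm, ocm, calibrant_set, stage)."""
        return {**keys, **asdict(self)}


def elution_time(calibrant_rts_in_ocm) -> float:
    """Elution time of an OCM: the maximum calibrant RT measured in it."""
    rts = np.asarray(calibrant_rts_in_ocm, dtype=float)
    if rts.size == 0:
        raise ValueError("elution_time: empty calibrant RT vector")
    if not np.all(rts > 0):
        raise ValueError("elution_time: calibrant RTs must be positive")
    return float(rts.max())


def error_ret(pred: float, ref: float, et: float) -> float:
    """Absolute RT error as % of elution time: ``100 * |pred - ref| / et``."""
    if et <= 0:
        raise ValueError(f"error_ret: elution time must be positive, got {et}")
    return float(100.0 * np.abs(np.asarray(pred) - np.asarray(ref)) / et)


def r_squared(x, y) -> float:
    """Square of the Pearson correlation coefficient between two vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("r_squared: x and y must be 1-D of equal length")
    if x.size < 2:
        raise ValueError("r_squared: need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r_squared: zero variance in input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def summarize(pred, ref, et: float, signed_me: bool = True) -> EvalMetrics:
    """Compute all elution-time-relative metrics for paired RT vectors.

    Parameters
    ----------
    pred, ref
        Equal-length vectors of predicted/projected and reference RTs (min).
    et
        Elution time of the output method (min).
    signed_me
        If True (default), ``me_ret`` is the signed mean error (bias); if
        False it is the mean absolute error, for sensitivity checks.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape or pred.ndim != 1:
        raise ValueError("summarize: pred and ref must be 1-D of equal length")
    if pred.size == 0:
        raise ValueError("summarize: empty input")
    if et <= 0:
        raise ValueError("summarize: elution time must be positive")
    err = pred - ref
    rmse_min = float(np.sqrt(np.mean(err**2)))
    mae_min = float(np.mean(np.abs(err)))
    me = float(np.mean(err)) if signed_me else mae_min
    if pred.size >= 2 and np.ptp(pred) > 0 and np.ptp(ref) > 0:
        r2 = r_squared(pred, ref)
    else:
        r2 = float("nan")
    return EvalMetrics(
        elution_time=float(et),
        rmse_ret=100.0 * rmse_min / et,
        mede_ret=float(100.0 * np.median(np.abs(err)) / et),
        me_ret=100.0 * me / et,
        mae_min=mae_min,
        rmse_min=rmse_min,
        r2=r2,
        n=int(pred.size),
    )
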