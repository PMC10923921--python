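"""Post-projection calibration: ReICM selection, RePRT, and error accounting.

Directly projecting RTs from an input method (ICM) onto an output method
(OCM) degrades as the two LC setups diverge — mobile-phase additives reorder
elution for whole classes of molecules, and the projection curve fitted on
calibrants cannot express that.  The remedy implemented here: run a locally
available *reference input method* (ReICM) whose elution order closely
matches the ICM, fit a second GP (the ReProjection model) from ReICM to OCM
on the same calibrants, and compare each candidate's projected RT not with
the OCM experimental RT but with the *reference-projected RT* (RePRT) of the
unknown — both numbers then carry the same setup-specific distortion, which
cancels in the comparison.

Diagnostics:

* ``r2_b`` — squared Pearson correlation of calibrant RTs between ICM and
  OCM; predicts projection accuracy.
* ``r2_c`` — same between ICM and ReICM; predicts calibration accuracy and
  drives automatic ReICM selection (argmax over candidate methods).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import CalibrantSet, RTTable
from .metrics import elution_time, error_ret, r_squared
from .projection import ProjectionModel, fit_projection, project

__all__ = [
    "CalibrationContext",
    "CalibratedPrediction",
    "QualityAdvisory",
    "select_reference",
    "build_context",
    "calibrate",
    "quality_estimate",
]

logger = logging.getLogger(__name__)

#: r2_c below this raises a low-similarity flag on the context
LOW_SIMILARITY_R2C = 0.95

#: r2_c at or above this, with a representative calibrant set, has been
#: associated with calibration RMSE_Ret below ~3% of elution time
HIGH_CONFIDENCE_R2C = 0.992

#: calibrant sets with too few retention behaviors make r2-based quality
#: estimates unreliable
UNRELIABLE_SETS = frozenset({"E"})


@dataclass(frozen=True)
class CalibrationContext:
    """Everything needed to calibrate projections for one (ICM, ReICM, OCM)."""

    icm: str
    reicm: str
    ocm: str
    main_model: ProjectionModel  # ICM -> OCM
    re_model: ProjectionModel  # ReICM -> OCM
    calibrant_set: CalibrantSet
    r2_b: float
    r2_c: float
    elution_time: float
    low_similarity: bool  # True when r2_c < LOW_SIMILARITY_R2C


@dataclass(frozen=True)
class CalibratedPrediction:
    """One unknown's projected RT and its RePRT reference in the OCM."""

    molecule_id: str
    projected_rt: float  # main model output, minutes
    reprt: float  # ReProjection model output, minutes
    err_after: float  # % of elution time, projected vs RePRT
    err_before: float | None = None  # % vs OCM experimental RT, when known


@dataclass(frozen=True)
class QualityAdvisory:
    """Advisory accuracy band derived from r2_b / r2_c (never blocking)."""

    band: str  # "high" | "moderate" | "low"
    message: str
    reliable: bool  # False for calibrant sets that defeat the estimate


def select_reference(
    icm: str,
    candidate_cms: list[str],
    table: RTTable,
    calibrants: CalibrantSet,
) -> tuple[str, float]:
    """Pick the ReICM most similar to the ICM in calibrant elution order.

    Similarity is the squared Pearson correlation (r2_c) of calibrant RTs
    between the ICM and each candidate; the argmax wins, ties broken by
    lexicographically smaller cm_id.  Candidates lacking complete calibrant
    coverage are skipped.
    """
    icm_rts = table.rts_in_cm(icm, calibrants.molecule_ids)
    best: tuple[float, str] | None = None
    for cm in sorted(candidate_cms):
        if cm == icm:
            continue
        try:
            cand_rts = table.rts_in_cm(cm, calibrants.molecule_ids)
        except KeyError:
            logger.warning("ReICM candidate %s lacks calibrant coverage; skipped", cm)
            continue
        r2c = r_squared(icm_rts, cand_rts)
        if best is None or r2c > best[0]:
            best = (r2c, cm)
    if best is None:
        raise ValueError(
            f"no ReICM candidate with complete calibrant coverage for ICM {icm!r}"
        )
    return best[1], best[0]


def build_context(
    icm: str,
    reicm: str,
    ocm: str,
    table: RTTable,
    calibrants: CalibrantSet,
    calibrant_rt_overrides: dict[str, float] | None = None,
    seed: int = 0,
    n_restarts: int = 5,
) -> CalibrationContext:
    """Fit the main (ICM->OCM) and ReProjection (ReICM->OCM) models.

    ``calibrant_rt_overrides`` substitutes per-calibrant RTs on the ICM side
    only — this supports mixed calibration where some calibrants have no
    experimental RT on the ICM and a QSRR-predicted RT is used instead.
    Calibrants missing in any of the three methods (and not overridden on
    the ICM) are dropped; at least 5 must survive.
    """
    overrides = calibrant_rt_overrides or {}
    usable, missing = [], []
    for mol in calibrants.molecule_ids:
        has_icm = mol in overrides or table.has(mol, icm)
        if has_icm and table.has(mol, reicm) and table.has(mol, ocm):
            usable.append(mol)
        else:
            missing.append(mol)
    if len(usable) < 5:
        raise ValueError(
            f"insufficient calibrants for ({icm}, {reicm}, {ocm}): "
            f"missing {sorted(missing)}"
        )
    if missing:
        logger.info(
            "context (%s, %s, %s): %d/%d calibrants usable (dropped %s)",
            icm, reicm, ocm, len(usable), len(calibrants), sorted(missing),
        )

    icm_rts = np.array(
        [overrides[m] if m in overrides else table.rt(m, icm) for m in usable],
        dtype=float,
    )
    reicm_rts = table.rts_in_cm(reicm, usable)
    ocm_rts = table.rts_in_cm(ocm, usable)

    main_model = fit_projection(
        icm_rts, ocm_rts, source_cm=icm, target_cm=ocm, seed=seed, n_restarts=n_restarts
    )
    re_model = fit_projection(
        reicm_rts, ocm_rts, source_cm=reicm, target_cm=ocm, seed=seed, n_restarts=n_restarts
    )
    r2_b = r_squared(icm_rts, ocm_rts)
    r2_c = r_squared(icm_rts, reicm_rts)
    if r2_c < LOW_SIMILARITY_R2C:
        logger.warning(
            "ICM %s vs ReICM %s: low elution-order similarity (r2_c=%.3f)",
            icm, reicm, r2_c,
        )
    return CalibrationContext(
        icm=icm,
        reicm=reicm,
        ocm=ocm,
        main_model=main_model,
        re_model=re_model,
        calibrant_set=CalibrantSet(calibrants.name, tuple(usable)),
        r2_b=r2_b,
        r2_c=r2_c,
        elution_time=elution_time(ocm_rts),
        low_similarity=r2_c < LOW_SIMILARITY_R2C,
    )


def calibrate(
    context: CalibrationContext,
    unknowns_rt_in_icm: dict[str, float],
    unknowns_rt_in_reicm: dict[str, float],
    ocm_experimental: dict[str, float] | None = None,
) -> list[CalibratedPrediction]:
    """Project unknowns onto the OCM and compute errors vs RePRT.

    For each unknown: ``projected_rt`` comes from the main model applied to
    its ICM RT (experimental or predicted); ``reprt`` from the ReProjection
    model applied to its ReICM experimental RT.  ``err_after`` compares the
    two as % of elution time.  When OCM experimental RTs are supplied
    (validation mode), ``err_before`` compares projected RT with them.
    Unknowns missing in either RT map are skipped with a warning.
    """
    ids = [m for m in unknowns_rt_in_icm if m in unknowns_rt_in_reicm]
    skipped = sorted(
        set(unknowns_rt_in_icm).symmetric_difference(unknowns_rt_in_reicm)
    )
    if skipped:
        logger.warning("calibrate: skipped %d unknowns missing an RT: %s",
                       len(skipped), skipped[:10])
    if not ids:
        return []
    x_icm = np.array([unknowns_rt_in_icm[m] for m in ids], dtype=float)
    x_re = np.array([unknowns_rt_in_reicm[m] for m in ids], dtype=float)
    projected = project(context.main_model, x_icm).mean
    reprt = project(context.re_model, x_re).mean
    out = []
    for i, mol in enumerate(ids):
        err_before = None
        if ocm_experimental is not None and mol in ocm_experimental:
            err_before = error_ret(
                projected[i], ocm_experimental[mol], context.elution_time
            )
        out.append(
            CalibratedPrediction(
                molecule_id=mol,
                projected_rt=float(projected[i]),
                reprt=float(reprt[i]),
                err_after=error_ret(projected[i], reprt[i], context.elution_time),
                err_before=err_before,
            )
        )
    return out


def quality_estimate(
    r2_b: float, r2_c: float, calibrant_set_name: str = "B"
) -> QualityAdvisory:
    """Advisory accuracy band from the r2 diagnostics.

    High elution-order similarity between ICM and ReICM (r2_c >= 0.992, with
    a behavior-representative calibrant set) has been associated with
    calibration RMSE_Ret below ~3% of elution time.  The estimate degrades
    monotonically with r2_c and is unreliable for calibrant sets covering
    too few retention behaviors.
    """
    for name, v in (("r2_b", r2_b), ("r2_c", r2_c)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    reliable = calibrant_set_name not in UNRELIABLE_SETS
    if r2_c >= HIGH_CONFIDENCE_R2C:
        band, msg = "high", "calibration RMSE_Ret expected < 3.0% of elution time"
    elif r2_c >= LOW_SIMILARITY_R2C:
        band, msg = "moderate", "calibration expected usable; consider a closer ReICM"
    else:
        band, msg = "low", (
            "low ICM-ReICM elution-order similarity; calibration accuracy "
            "cannot be vouched for"
        )
    if not reliable:
        msg += (
            f" [estimate unreliable: calibrant set {calibrant_set_name!r} covers "
            "too few retention behaviors]"
        )
    return QualityAdvisory(band=band, message=msg, reliable=reliable)
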