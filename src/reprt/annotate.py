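"""RT-based filtering and ranking of putative candidates for unknowns.

In untargeted LC-MS annotation, each detected-but-unidentified feature (an
"unknown") comes with a list of putative candidate structures.  Their
predicted RTs, projected onto the local output method, are compared with a
per-unknown reference RT — the OCM experimental RT before calibration, or
the RePRT after.  Candidates whose RT error (as % of elution time) exceeds a
threshold — by default twice the output method's RMSE_Ret — are deemed
negative; surviving candidates are ranked by ascending RT error.

Candidate tables are pandas DataFrames with columns ``unknown_id``,
``candidate_id``, ``projected_rt`` and optionally ``is_true`` (at most one
true identity per unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "filter_threshold",
    "filter_candidates",
    "confusion",
    "rank_candidates",
    "top_n_summary",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("unknown_id", "candidate_id", "projected_rt")


@dataclass(frozen=True)
class ConfusionCounts:
    """Filtering outcome counts over labeled candidates.

    TP: true identities within the threshold; FN: true identities filtered
    out; FP: false identities accepted; TN: false identities filtered out.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else float("nan")

    @property
    def tnr(self) -> float:
        return 1.0 - self.fpr

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def filter_threshold(ocm_rmse_ret: float) -> float:
    """RT-error threshold for an OCM: twice its projection RMSE_Ret (%)."""
    if ocm_rmse_ret <= 0:
        raise ValueError(f"filter_threshold: RMSE_Ret must be positive, got {ocm_rmse_ret}")
    return 2.0 * ocm_rmse_ret


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"candidate table missing columns {missing}")


def _err_pct(table: pd.DataFrame, reference_rt: dict[str, float], et: float) -> pd.Series:
    if et <= 0:
        raise ValueError("elution time must be positive")
    missing = sorted(set(table["unknown_id"]) - set(reference_rt))
    if missing:
        raise ValueError(f"no reference RT for unknowns {missing[:10]}")
    ref = table["unknown_id"].map(reference_rt)
    return 100.0 * (table["projected_rt"] - ref).abs() / et


def filter_candidates(
    table: pd.DataFrame,
    reference_rt: dict[str, float],
    elution_time: float,
    threshold_pct: float,
) -> pd.Series:
    """Positive/negative decision per candidate row.

    A row is positive iff its RT error (% of elution time vs the unknown's
    reference RT) is at or below ``threshold_pct``; errors exactly on the
    boundary count as positive.  Returns a boolean Series aligned with
    ``table``.
    """
    _check_table(table)
    if threshold_pct <= 0:
        raise ValueError("threshold_pct must be positive")
    return _err_pct(table, reference_rt, elution_time) <= threshold_pct


def confusion(table: pd.DataFrame, decisions: pd.Series) -> ConfusionCounts:
    """Count TP/FP/TN/FN over labeled candidates.

    Rows without an ``is_true`` label are excluded (count logged).
    """
    _check_table(table)
    if "is_true" not in table.columns:
        raise ValueError("confusion: table has no is_true labels")
    labeled = table["is_true"].notna()
    n_dropped = int((~labeled).sum())
    if n_dropped:
        logger.info("confusion: excluded %d unlabeled candidates", n_dropped)
    truth = table.loc[labeled, "is_true"].astype(bool)
    pos = decisions.loc[labeled].astype(bool)
    return ConfusionCounts(
        tp=int((truth & pos).sum()),
        fp=int((~truth & pos).sum()),
        tn=int((~truth & ~pos).sum()),
        fn=int((truth & ~pos).sum()),
    )


def rank_candidates(
    table: pd.DataFrame,
    reference_rt: dict[str, float],
    elution_time: float,
) -> pd.DataFrame:
    """Rank candidates per unknown by ascending RT error (rank 1 = best).

    Exact error ties are broken by lexicographic candidate_id, so the
    ranking is a stable total order independent of input row order.
    Returns a copy of ``table`` with ``err_pct`` and ``rank`` columns.
    """
    _check_table(table)
    out = table.copy()
    out["err_pct"] = _err_pct(out, reference_rt, elution_time)
    out = out.sort_values(
        ["unknown_id", "err_pct", "candidate_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = out.groupby("unknown_id").cumcount() + 1
    return out


def top_n_summary(ranked: pd.DataFrame, n: int) -> int:
    """Number of unknowns whose true identity ranks within the top ``n``."""
    if "is_true" not in ranked.columns or "rank" not in ranked.columns:
        raise ValueError("top_n_summary: need is_true labels and ranks")
    if n <= 0:
        return 0
    hits = ranked[(ranked["is_true"].fillna(False).astype(bool)) & (ranked["rank"] <= n)]
    return int(hits["unknown_id"].nunique())
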