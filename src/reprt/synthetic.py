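"""Synthetic multi-CM retention-time data with known ground truth.

The generator emulates the statistical structure the calibration method
relies on, so every pipeline stage is testable without measured data:

* each molecule carries a latent hydrophobicity ``u`` in [0, 1];
* each CM maps ``u`` to an RT through a monotone sigmoid warp (dead-time
  plateau, steep mid-gradient rise, late plateau), with warp parameters
  drawn around family-level means so methods sharing a mobile-phase family
  have similar elution order;
* molecules belong to retention-behavior groups: *general* groups follow
  the warp exactly, *non-retained* groups sit near the dead time, and
  *outgeneral* groups receive an additive group-by-family offset that
  reorders elution between families — the distortion post-projection
  calibration exists to absorb;
* i.i.d. Gaussian measurement noise on every RT.

Defaults mirror a realistic multi-CM RT database: 330 molecules, 30 CMs in
4 mobile-phase families, 25 behavior groups, 0.05 min noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChromMethod, RTTable, wide_to_long

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_dataset", "generate_candidates"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults are the study conditions."""

    n_molecules: int = 330
    n_cms: int = 30
    n_families: int = 4
    n_groups: int = 25
    frac_outgeneral: float = 0.20
    frac_nonretained: float = 0.08
    noise_sd: float = 0.05  # minutes
    run_times: tuple[float, ...] | None = None  # minutes; cycled over CMs
    dead_time_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_outgeneral <= 1.0:
            raise ValueError("frac_outgeneral must be in [0, 1]")
        if not 0.0 <= self.frac_nonretained <= 1.0:
            raise ValueError("frac_nonretained must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_groups > self.n_molecules:
            raise ValueError("n_groups cannot exceed n_molecules")


DEFAULT_RUN_TIMES = (10.0, 15.0, 21.0, 30.0, 45.0, 60.0)

#: spread of outgeneral group-by-family offsets, as a fraction of the
#: CM's effective gradient span
OUTGENERAL_DELTA_SD = 0.12


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    u: pd.Series  # latent hydrophobicity per molecule
    groups: dict[str, int]  # molecule -> behavior group (1-based)
    group_kind: dict[int, str]  # group -> {general, nonretained, outgeneral}
    delta_frac: pd.DataFrame  # group x family offsets (fraction of span)
    warps: pd.DataFrame  # per-CM: a, b, t0, run_time, family
    rt_clean: pd.DataFrame = field(repr=False)  # noiseless molecules x CMs


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[RTTable, list[ChromMethod], SyntheticTruth]:
    """Draw a full multi-CM RT dataset; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    molecules = [f"M{i:04d}" for i in range(config.n_molecules)]
    cms = [f"CM{i + 1:02d}" for i in range(config.n_cms)]
    run_times = config.run_times or DEFAULT_RUN_TIMES

    u = pd.Series(rng.uniform(0.0, 1.0, config.n_molecules), index=molecules, name="u")

    # behavior groups: the first few are non-retained, the next outgeneral,
    # the rest general; molecules assigned uniformly
    n_nr = int(round(config.frac_nonretained * config.n_groups))
    if config.frac_nonretained > 0:
        n_nr = max(n_nr, 1)
    n_og = int(round(config.frac_outgeneral * config.n_groups))
    if config.frac_outgeneral > 0:
        n_og = max(n_og, 1)
    if n_nr + n_og > config.n_groups:
        raise ValueError("behavior fractions leave no general groups")
    group_kind = {}
    for g in range(1, config.n_groups + 1):
        if g <= n_nr:
            group_kind[g] = "nonretained"
        elif g <= n_nr + n_og:
            group_kind[g] = "outgeneral"
        else:
            group_kind[g] = "general"
    group_of = rng.integers(1, config.n_groups + 1, config.n_molecules)
    groups = dict(zip(molecules, map(int, group_of)))

    # CMs in contiguous family blocks; warp parameters around family means
    family_of_cm = [c * config.n_families // config.n_cms for c in range(config.n_cms)]
    fam_a = rng.uniform(5.0, 9.0, config.n_families)
    fam_b = rng.uniform(0.40, 0.60, config.n_families)
    warp_rows = []
    for c, cm in enumerate(cms):
        fam = family_of_cm[c]
        T = float(run_times[c % len(run_times)])
        warp_rows.append(
            {
                "cm_id": cm,
                "family": fam,
                "a": float(fam_a[fam] * np.exp(rng.normal(0.0, 0.15))),
                "b": float(np.clip(fam_b[fam] + rng.normal(0.0, 0.05), 0.1, 0.9)),
                "t0": config.dead_time_frac * T,
                "run_time": T,
            }
        )
    warps = pd.DataFrame(warp_rows).set_index("cm_id")

    # outgeneral offsets per (group, family), zero for the reference family 0
    delta = pd.DataFrame(
        0.0, index=pd.RangeIndex(1, config.n_groups + 1, name="group_id"),
        columns=pd.RangeIndex(config.n_families, name="family"),
    )
    for g in range(1, config.n_groups + 1):
        if group_kind[g] == "outgeneral":
            delta.loc[g, 1:] = rng.normal(0.0, OUTGENERAL_DELTA_SD, config.n_families - 1)

    # noiseless RTs
    rt_clean = pd.DataFrame(index=pd.Index(molecules, name="molecule_id"),
                            columns=pd.Index(cms, name="cm_id"), dtype=float)
    uu = u.to_numpy()
    kinds = np.array([group_kind[groups[m]] for m in molecules])
    group_arr = np.array([groups[m] for m in molecules])
    base = {}
    for cm in cms:
        w = warps.loc[cm]
        t0, T = float(w["t0"]), float(w["run_time"])
        rt = t0 + (T - t0) * _sigmoid(w["a"] * (uu - w["b"]))
        # non-retained: pinned just past the dead time, weakly ordered by u
        nr = kinds == "nonretained"
        rt[nr] = t0 * (1.0 + 0.2 * uu[nr])
        base[cm] = rt

    # outgeneral offsets are shared exactly by every molecule of a
    # (group, family); an offset that would push any member outside
    # (0, run_time] in any CM of the family is halved for the whole pair
    for _ in range(64):
        bad_pairs = set()
        for cm in cms:
            w = warps.loc[cm]
            t0, T, fam = float(w["t0"]), float(w["run_time"]), int(w["family"])
            shift = delta.loc[group_arr, fam].to_numpy(dtype=float) * (T - t0)
            rt = base[cm] + shift
            for g in np.unique(group_arr[(rt <= 0) | (rt > T)]):
                bad_pairs.add((int(g), fam))
        if not bad_pairs:
            break
        logger.info("shrinking infeasible outgeneral offsets: %s", sorted(bad_pairs))
        for g, fam in bad_pairs:
            delta.loc[g, fam] *= 0.5

    for cm in cms:
        w = warps.loc[cm]
        fam = int(w["family"])
        span = float(w["run_time"]) - float(w["t0"])
        rt_clean[cm] = base[cm] + delta.loc[group_arr, fam].to_numpy(dtype=float) * span

    noisy = rt_clean + rng.normal(0.0, config.noise_sd, rt_clean.shape)
    noisy = noisy.clip(lower=1e-3)
    for cm in cms:
        noisy[cm] = noisy[cm].clip(upper=warps.loc[cm, "run_time"])

    table = wide_to_long(noisy)
    methods = [
        ChromMethod(
            cm_id=cm,
            column="synthetic C18",
            mobile_phase_a="H2O (synthetic)",
            mobile_phase_b="MeOH (synthetic)",
            additive_family=f"F{int(warps.loc[cm, 'family']) + 1}",
            gradient=(
                (0.0, 0.3, 5.0),
                (round(0.85 * warps.loc[cm, "run_time"], 2), 0.3, 100.0),
                (float(warps.loc[cm, "run_time"]), 0.3, 5.0),
            ),
            run_time=float(warps.loc[cm, "run_time"]),
            temperature=30.0,
        )
        for cm in cms
    ]
    truth = SyntheticTruth(
        u=u, groups=groups, group_kind=group_kind,
        delta_frac=delta, warps=warps, rt_clean=rt_clean,
    )
    return table, methods, truth


def generate_candidates(
    truth: SyntheticTruth,
    unknowns: list[str],
    n_per_unknown: int,
    decoy_rt_model: str = "uniform",
    seed: int = 0,
    cm_id: str | None = None,
    qsrr_error_sd: float = 0.3,
) -> pd.DataFrame:
    """Candidate lists for unknowns, with one labeled true identity each.

    The true candidate's predicted RT is the unknown's noiseless RT in
    ``cm_id`` (default: first CM) plus a QSRR-like Gaussian error; decoys
    draw their RT ``uniform`` over the CM's RT range or ``near_true`` around
    the true RT.  Returns a DataFrame with columns ``unknown_id``,
    ``candidate_id``, ``predicted_rt``, ``is_true``.
    """
    if n_per_unknown < 2:
        raise ValueError("need at least 2 candidates per unknown (true + decoy)")
    if decoy_rt_model not in ("uniform", "near_true"):
        raise ValueError(f"unknown decoy_rt_model {decoy_rt_model!r}")
    cm = cm_id or truth.rt_clean.columns[0]
    missing = [m for m in unknowns if m not in truth.rt_clean.index]
    if missing:
        raise KeyError(f"unknowns not in truth: {missing[:10]}")
    rng = np.random.default_rng(seed)
    t0 = float(truth.warps.loc[cm, "t0"])
    T = float(truth.warps.loc[cm, "run_time"])
    rows = []
    for unk in unknowns:
        true_rt = float(truth.rt_clean.loc[unk, cm])
        rts = np.empty(n_per_unknown)
        rts[0] = max(true_rt + rng.normal(0.0, qsrr_error_sd), 1e-3)
        if decoy_rt_model == "uniform":
            rts[1:] = rng.uniform(t0, T, n_per_unknown - 1)
        else:
            rts[1:] = np.clip(
                true_rt + rng.normal(0.0, 5.0 * qsrr_error_sd, n_per_unknown - 1),
                1e-3, T,
            )
        for k in range(n_per_unknown):
            rows.append(
                {
                    "unknown_id": unk,
                    "candidate_id": f"{unk}_cand{k:03d}",
                    "predicted_rt": float(rts[k]),
                    "is_true": k == 0,
                }
            )
    return pd.DataFrame(rows)
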