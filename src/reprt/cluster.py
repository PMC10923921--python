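"""Retention-behavior clustering and calibrant selection.

Molecules measured across many chromatographic methods (CMs) trace an
*elution profile*: their RT vector over CMs.  Most molecules follow the bulk
monotone trend between any two CMs ("general" behavior), but some groups
swap elution order between mobile-phase families ("outgeneral" behavior) and
others barely retain at all.  A self-organizing map (SOM) over normalized
profiles groups molecules by this behavior; calibrants are then chosen so
that every behavior group is represented and the full RT range of each CM is
spanned.

The SOM here is a plain online Kohonen map (rectangular grid, Gaussian
neighborhood, linearly decaying radius and learning rate) with a mandatory
seed so that clustering is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CalibrantSet, RTTable, to_wide

__all__ = [
    "SelfOrganizingMap",
    "BehaviorAssignment",
    "normalize_profiles",
    "som_cluster",
    "select_calibrants",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Profile normalization
# ---------------------------------------------------------------------------


def normalize_profiles(matrix: pd.DataFrame, mode: str = "per_cm_elution") -> pd.DataFrame:
    """Normalize a molecules x CMs RT matrix so CMs of different lengths
    contribute comparably.

    ``per_cm_elution`` divides each CM column by its elution time (column
    maximum), giving values in (0, 1].  ``per_cm_minmax`` maps each column's
    min to 0 and max to 1.  ``none`` is the identity.
    """
    if matrix.isna().any().any():
        raise ValueError(
            "normalize_profiles: matrix has missing cells; restrict to fully "
            "observed molecules first"
        )
    if mode == "none":
        return matrix.copy()
    if mode == "per_cm_elution":
        return matrix / matrix.max(axis=0)
    if mode == "per_cm_minmax":
        span = matrix.max(axis=0) - matrix.min(axis=0)
        span = span.replace(0.0, 1.0)  # constant column maps to 0
        return (matrix - matrix.min(axis=0)) / span
    raise ValueError(f"unknown normalization mode {mode!r}")


# ---------------------------------------------------------------------------
# Self-organizing map
# ---------------------------------------------------------------------------


class SelfOrganizingMap:
    """Minimal online Kohonen SOM on a rectangular grid.

    Units live on a ``rows x cols`` grid; each holds a prototype vector in
    input space.  Training presents one random sample per iteration, moves
    the best-matching unit (BMU) and its grid neighbors toward it with a
    Gaussian neighborhood whose radius and learning rate decay linearly.
    """

    def __init__(
        self,
        rows: int,
        cols: int,
        n_features: int,
        seed: int,
        sigma0: float | None = None,
        learning_rate0: float = 0.5,
    ) -> None:
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be positive")
        self.rows, self.cols = rows, cols
        self.n_features = n_features
        self.rng = np.random.default_rng(seed)
        self.sigma0 = sigma0 if sigma0 is not None else max(rows, cols) / 2.0
        self.lr0 = learning_rate0
        # grid coordinates of each unit, shape (rows*cols, 2)
        self.coords = np.indices((rows, cols)).reshape(2, -1).T.astype(float)
        self.weights: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def fit(self, X: np.ndarray, epochs: int = 5000) -> "SelfOrganizingMap":
        """Train for ``epochs`` single-sample updates."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError("X must be 2-D with n_features columns")
        if X.shape[0] < self.n_units:
            logger.warning(
                "fewer samples (%d) than SOM units (%d); empty groups expected",
                X.shape[0],
                self.n_units,
            )
        # init prototypes from random samples (with replacement if needed)
        idx = self.rng.choice(X.shape[0], size=self.n_units, replace=X.shape[0] < self.n_units)
        self.weights = X[idx].copy()
        for t in range(epochs):
            frac = t / max(epochs - 1, 1)
            sigma = max(self.sigma0 * (1.0 - frac), 0.3)
            lr = self.lr0 * (1.0 - frac) + 1e-3
            x = X[self.rng.integers(X.shape[0])]
            bmu = int(np.argmin(((self.weights - x) ** 2).sum(axis=1)))
            d2 = ((self.coords - self.coords[bmu]) ** 2).sum(axis=1)
            h = np.exp(-d2 / (2.0 * sigma**2))
            self.weights += (lr * h)[:, None] * (x - self.weights)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Best-matching unit index (0-based, row-major) per sample."""
        if self.weights is None:
            raise RuntimeError("SOM is not fitted")
        X = np.asarray(X, dtype=float)
        d2 = ((X[:, None, :] - self.weights[None, :, :]) ** 2).sum(axis=2)
        return d2.argmin(axis=1)


@dataclass(frozen=True)
class BehaviorAssignment:
    """Molecule -> retention-behavior-group mapping with group prototypes.

    Groups are numbered 1..n_groups (row-major over the SOM grid); the
    prototype of a group is its unit's weight vector over CMs.
    """

    groups: dict[str, int]
    n_groups: int
    grid_shape: tuple[int, int]
    prototypes: pd.DataFrame  # index group_id 1..n_groups, columns CM ids

    def members(self, group_id: int) -> list[str]:
        return sorted(m for m, g in self.groups.items() if g == group_id)

    @property
    def nonempty_groups(self) -> list[int]:
        return sorted(set(self.groups.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.groups.items()), columns=["molecule_id", "group_id"]
        )


def som_cluster(
    profiles: pd.DataFrame,
    grid: tuple[int, int] = (5, 5),
    epochs: int = 5000,
    seed: int = 0,
) -> BehaviorAssignment:
    """Cluster normalized elution profiles into retention-behavior groups.

    ``profiles`` is a fully observed molecules x CMs matrix (normalize
    first).  The default 5x5 grid yields up to 25 behavior groups.  The same
    seed always reproduces the same assignment bit-for-bit.
    """
    if profiles.isna().any().any():
        raise ValueError("som_cluster: profiles contain missing cells")
    rows, cols = grid
    som = SelfOrganizingMap(rows, cols, profiles.shape[1], seed=seed)
    X = profiles.to_numpy(dtype=float)
    som.fit(X, epochs=epochs)
    units = som.predict(X)
    groups = {mol: int(u) + 1 for mol, u in zip(profiles.index, units)}
    prototypes = pd.DataFrame(
        som.weights,
        index=pd.RangeIndex(1, som.n_units + 1, name="group_id"),
        columns=profiles.columns,
    )
    return BehaviorAssignment(
        groups=groups,
        n_groups=som.n_units,
        grid_shape=(rows, cols),
        prototypes=prototypes,
    )


# ---------------------------------------------------------------------------
# Calibrant selection
# ---------------------------------------------------------------------------


def select_calibrants(
    assignment: BehaviorAssignment,
    table: RTTable,
    target_size: int,
    min_groups_covered: int,
    name: str = "auto",
    range_coverage: float = 0.90,
) -> CalibrantSet:
    """Greedy calibrant selection covering behavior groups and RT range.

    Pass 1 takes, for each non-empty behavior group in ascending group order,
    the molecule whose normalized profile is nearest the group prototype
    (ties broken by lexicographic molecule id).  Pass 2 extends the set with
    molecules that most enlarge the per-CM RT span until ``target_size`` is
    reached, so the calibrants cover at least ``range_coverage`` of each
    CM's full RT range.  The selection is nested: growing ``target_size``
    only appends molecules, never changes earlier picks.
    """
    if target_size < min_groups_covered:
        raise ValueError("target_size must be >= min_groups_covered")
    wide = to_wide(table)
    # calibrants must exist in every CM of the table
    full = wide.dropna(axis=0)
    eligible = [m for m in full.index if m in assignment.groups]
    if not eligible:
        raise ValueError("no fully observed molecules with a group assignment")
    full = full.loc[eligible]
    norm = normalize_profiles(full, "per_cm_elution")

    nonempty = [
        g for g in assignment.nonempty_groups
        if any(m in full.index for m in assignment.members(g))
    ]
    if len(nonempty) < min_groups_covered:
        uncoverable = sorted(set(range(1, assignment.n_groups + 1)) - set(nonempty))
        raise ValueError(
            f"only {len(nonempty)} groups coverable "
            f"(< {min_groups_covered}); empty/uncoverable groups: {uncoverable}"
        )

    selected: list[str] = []
    # pass 1: group medoids (nearest-to-prototype), ascending group id
    for g in nonempty:
        if len(selected) >= target_size:
            break
        members = [m for m in assignment.members(g) if m in full.index and m not in selected]
        if not members:
            continue
        proto = assignment.prototypes.loc[g, norm.columns].to_numpy(dtype=float)
        dists = ((norm.loc[members].to_numpy(dtype=float) - proto) ** 2).sum(axis=1)
        best = min(zip(dists, members))  # lexicographic tie-break via tuple
        selected.append(best[1])

    # pass 2: extend per-CM RT-range coverage
    lo, hi = full.min(axis=0), full.max(axis=0)
    full_span = (hi - lo).replace(0.0, np.nan)

    def coverage(sel: list[str]) -> pd.Series:
        sub = full.loc[sel]
        cov = (sub.max(axis=0) - sub.min(axis=0)) / full_span
        return cov.fillna(1.0)

    remaining = sorted(m for m in full.index if m not in selected)
    while len(selected) < target_size and remaining:
        cov = coverage(selected)
        # candidate gain: mean increase in per-CM coverage
        gains = []
        for m in remaining:
            cov_m = coverage(selected + [m])
            gains.append((-float((cov_m - cov).mean()), m))
        gains.sort()
        best_gain, best_mol = gains[0]
        if best_gain >= 0.0:  # no span left to gain: fill by profile spread
            # farthest-point fill keeps behavior diversity
            sel_mat = norm.loc[selected].to_numpy(dtype=float)
            far = [
                (-float(((norm.loc[m].to_numpy(dtype=float) - sel_mat) ** 2).sum(axis=1).min()), m)
                for m in remaining
            ]
            far.sort()
            best_mol = far[0][1]
        selected.append(best_mol)
        remaining.remove(best_mol)

    cov = coverage(selected)
    low = cov[cov < range_coverage]
    if not low.empty:
        logger.warning(
            "calibrant set %r spans < %.0f%% of the RT range in CMs %s",
            name,
            100 * range_coverage,
            list(low.index),
        )
    return CalibrantSet(name=name, molecule_ids=tuple(selected))
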