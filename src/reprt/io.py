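"""Reading, writing and validation of the toolkit's tabular inputs.

Formats handled here:

* **RT long table** (CSV): columns ``molecule_id,cm_id,rt_min[,replicate]``.
  One row per measured retention time; replicates are collapsed on read.
* **Chromatographic-method (CM) metadata** (JSON): one object per CM with
  column, mobile phases, additive family, gradient program, run time and
  temperature.
* **Calibrant sets** (JSON): ``{"name": ..., "molecule_ids": [...]}``.
* **Projection models** (JSON): kernel hyperparameters, training vectors and
  standardization constants — see :mod:`reprt.projection`.

All CSV files are comma-separated UTF-8 with a header row and "." as the
decimal separator.  Missing retention times are encoded as empty cells (CSV)
or ``null`` (JSON), never as sentinel numbers: retention times are strictly
positive.  Molecule and CM identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "RTValidationError",
    "ChromMethod",
    "CalibrantSet",
    "RTTable",
    "read_rt_table",
    "write_rt_table",
    "to_wide",
    "wide_to_long",
    "read_cm_metadata",
    "write_cm_metadata",
    "read_calibrant_set",
    "write_calibrant_set",
    "write_model",
    "read_model",
]

#: retention times are considered equal when they agree to this precision (min)
RT_PRECISION = 1e-6

ReplicatePolicy = Literal["mean", "median", "first"]


class SchemaError(ValueError):
    """A file does not conform to the declared column/field schema."""


class RTValidationError(ValueError):
    """Data violates a content invariant (e.g. non-positive retention time)."""


# ---------------------------------------------------------------------------
# Chromatographic method metadata
# ---------------------------------------------------------------------------

#: mobile-phase additive families seen in practice plus free-form labels for
#: synthetic data ("F1", "F2", ...).  Families are compared, not parsed.
KNOWN_ADDITIVE_FAMILIES = ("A1B1", "A2B2", "A3B3", "A4B4", "A5B5")


@dataclass(frozen=True)
class ChromMethod:
    """One complete LC setup: column, mobile phases, gradient, temperature.

    ``gradient`` is the programmed gradient table as tuples of
    (time [min], flow [mL/min], %B).  ``additive_family`` labels the
    mobile-phase additive composition and drives similarity grouping of
    output methods.
    """

    cm_id: str
    column: str = ""
    mobile_phase_a: str = ""
    mobile_phase_b: str = ""
    additive_family: str = "A1B1"
    gradient: tuple[tuple[float, float, float], ...] = ()
    run_time: float = 0.0
    temperature: float = 30.0

    def __post_init__(self) -> None:
        times = [g[0] for g in self.gradient]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise RTValidationError(
                f"CM {self.cm_id!r}: gradient times must be strictly increasing"
            )
        for t, flow, pct_b in self.gradient:
            if flow <= 0:
                raise RTValidationError(
                    f"CM {self.cm_id!r}: flow must be positive at t={t}"
                )
            if not 0.0 <= pct_b <= 100.0:
                raise RTValidationError(
                    f"CM {self.cm_id!r}: %B out of [0, 100] at t={t}"
                )
        if self.gradient and self.run_time < times[-1]:
            raise RTValidationError(
                f"CM {self.cm_id!r}: run_time {self.run_time} min is before the "
                f"last gradient breakpoint at {times[-1]} min"
            )

    def to_dict(self) -> dict:
        return {
            "cm_id": self.cm_id,
            "column": self.column,
            "mobile_phase_a": self.mobile_phase_a,
            "mobile_phase_b": self.mobile_phase_b,
            "additive_family": self.additive_family,
            "gradient": [list(g) for g in self.gradient],
            "run_time": self.run_time,
            "temperature": self.temperature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChromMethod":
        try:
            gradient = tuple(
                (float(t), float(flow), float(pct)) for t, flow, pct in d.get("gradient", ())
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"CM {d.get('cm_id', '?')!r}: malformed gradient tuple ({exc})"
            ) from exc
        return cls(
            cm_id=str(d["cm_id"]),
            column=str(d.get("column", "")),
            mobile_phase_a=str(d.get("mobile_phase_a", "")),
            mobile_phase_b=str(d.get("mobile_phase_b", "")),
            additive_family=str(d.get("additive_family", "A1B1")),
            gradient=gradient,
            run_time=float(d.get("run_time", gradient[-1][0] if gradient else 0.0)),
            temperature=float(d.get("temperature", 30.0)),
        )


# ---------------------------------------------------------------------------
# Calibrant sets
# ---------------------------------------------------------------------------

#: minimum calibrants for a stable 1-D GP projection fit
MIN_CALIBRANTS = 5


@dataclass(frozen=True)
class CalibrantSet:
    """A named, ordered list of calibrant molecule ids (e.g. set "B")."""

    name: str
    molecule_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.molecule_ids)) != len(self.molecule_ids):
            dupes = pd.Series(self.molecule_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise RTValidationError(
                f"calibrant set {self.name!r}: duplicate molecule ids {dupes}"
            )
        if len(self.molecule_ids) < MIN_CALIBRANTS:
            raise RTValidationError(
                f"calibrant set {self.name!r}: needs at least {MIN_CALIBRANTS} "
                f"molecules, got {len(self.molecule_ids)}"
            )

    def __len__(self) -> int:
        return len(self.molecule_ids)


# ---------------------------------------------------------------------------
# RT tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RTTable:
    """Aggregated long-form retention-time table.

    One row per (molecule_id, cm_id), retention time in minutes.  Construct
    through :func:`read_rt_table` or :meth:`from_records`; the constructor
    validates positivity and uniqueness.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"molecule_id", "cm_id", "rt"}
        missing = required - set(self.df.columns)
        if missing:
            raise SchemaError(f"RTTable missing columns: {sorted(missing)}")
        bad = self.df.index[~(self.df["rt"] > 0)].tolist()
        if bad:
            raise RTValidationError(
                f"non-positive retention time at rows {bad[:10]}"
            )
        if self.df.duplicated(subset=["molecule_id", "cm_id"]).any():
            raise RTValidationError(
                "more than one aggregated rt for some (molecule_id, cm_id)"
            )

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float]]
    ) -> "RTTable":
        df = pd.DataFrame(records, columns=["molecule_id", "cm_id", "rt"])
        df["molecule_id"] = df["molecule_id"].astype(str)
        df["cm_id"] = df["cm_id"].astype(str)
        return cls(df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def molecules(self) -> list[str]:
        return sorted(self.df["molecule_id"].unique())

    @property
    def cms(self) -> list[str]:
        return sorted(self.df["cm_id"].unique())

    def rt(self, molecule_id: str, cm_id: str) -> float:
        """Retention time of one molecule in one CM; KeyError if absent."""
        sel = self.df[
            (self.df["molecule_id"] == molecule_id) & (self.df["cm_id"] == cm_id)
        ]
        if sel.empty:
            raise KeyError(f"no RT for molecule {molecule_id!r} in CM {cm_id!r}")
        return float(sel["rt"].iloc[0])

    def rts_in_cm(self, cm_id: str, molecule_ids: Sequence[str]) -> np.ndarray:
        """RT vector for ``molecule_ids`` in ``cm_id`` (KeyError on any gap)."""
        wide = self.df[self.df["cm_id"] == cm_id].set_index("molecule_id")["rt"]
        missing = [m for m in molecule_ids if m not in wide.index]
        if missing:
            raise KeyError(
                f"molecules missing in CM {cm_id!r}: {sorted(missing)[:10]}"
            )
        return wide.loc[list(molecule_ids)].to_numpy(dtype=float)

    def has(self, molecule_id: str, cm_id: str) -> bool:
        return bool(
            (
                (self.df["molecule_id"] == molecule_id)
                & (self.df["cm_id"] == cm_id)
            ).any()
        )

    def validate_against(self, cms: Sequence[ChromMethod]) -> None:
        """Check every cm_id resolves to supplied metadata."""
        known = {c.cm_id for c in cms}
        unknown = sorted(set(self.df["cm_id"]) - known)
        if unknown:
            raise RTValidationError(f"cm_ids without metadata: {unknown}")


def read_rt_table(path: str | Path, replicate_policy: ReplicatePolicy = "mean") -> RTTable:
    """Read a long-format RT CSV and collapse replicates.

    The file must contain ``molecule_id``, ``cm_id`` and ``rt_min`` columns;
    an optional ``replicate`` column is ignored beyond aggregation.  Replicate
    measurements of the same (molecule, CM) pair are collapsed with the given
    policy (arithmetic mean by default).
    """
    if replicate_policy not in ("mean", "median", "first"):
        raise ValueError(f"unknown replicate_policy {replicate_policy!r}")
    df = pd.read_csv(path, dtype={"molecule_id": str, "cm_id": str})
    for col in ("molecule_id", "cm_id", "rt_min"):
        if col not in df.columns:
            raise SchemaError(f"RT table {path}: missing required column {col!r}")
    bad = df.index[~(df["rt_min"] > 0)].tolist()
    if bad:
        raise RTValidationError(
            f"RT table {path}: non-positive rt_min at rows {bad[:10]}"
        )
    agg = (
        df.groupby(["molecule_id", "cm_id"], sort=False)["rt_min"]
        .agg(replicate_policy)
        .reset_index()
        .rename(columns={"rt_min": "rt"})
    )
    return RTTable(agg)


def write_rt_table(table: RTTable, path: str | Path) -> None:
    out = table.df.rename(columns={"rt": "rt_min"})
    out.to_csv(path, index=False)


def to_wide(table: RTTable) -> pd.DataFrame:
    """Pivot to a molecules x CMs matrix of retention times (NaN = missing)."""
    wide = table.df.pivot(index="molecule_id", columns="cm_id", values="rt")
    return wide.sort_index(axis=0).sort_index(axis=1)


def wide_to_long(wide: pd.DataFrame) -> RTTable:
    """Inverse of :func:`to_wide`; drops missing cells."""
    long = (
        wide.rename_axis(index="molecule_id", columns="cm_id")
        .stack()
        .rename("rt")
        .reset_index()
    )
    return RTTable(long)


# ---------------------------------------------------------------------------
# JSON helpers
# ---------------------------------------------------------------------------


def read_cm_metadata(path: str | Path) -> list[ChromMethod]:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise SchemaError(f"{path}: expected a JSON array of CM objects")
    return [ChromMethod.from_dict(d) for d in data]


def write_cm_metadata(cms: Sequence[ChromMethod], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([c.to_dict() for c in cms], fh, indent=1)


def read_calibrant_set(path: str | Path) -> CalibrantSet:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    try:
        return CalibrantSet(str(data["name"]), tuple(str(m) for m in data["molecule_ids"]))
    except KeyError as exc:
        raise SchemaError(f"{path}: calibrant set missing field {exc}") from exc


def write_calibrant_set(cal: CalibrantSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"name": cal.name, "molecule_ids": list(cal.molecule_ids)}, fh, indent=1)


def write_model(model, path: str | Path) -> None:
    """Serialize a fitted :class:`~reprt.projection.ProjectionModel` to JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model.to_dict(), fh)


def read_model(path: str | Path):
    from .projection import ProjectionModel

    with open(path, encoding="utf-8") as fh:
        return ProjectionModel.from_dict(json.load(fh))
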