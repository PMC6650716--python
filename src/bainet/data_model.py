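"""Domain types and I/O for bai visit data.

A "visit" is one social unit (a gorilla group or a solitary male) recorded at
a forest clearing (bai) on one observation day.  All downstream analysis works
on the binary units x days :class:`PresenceMatrix`; calendar dates are
converted once to 0-based integer day indices within the study interval so
that later stages never touch calendars.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "VisitRecord",
    "UnitInfo",
    "StudyPeriod",
    "PresenceMatrix",
    "read_visits",
    "write_visits",
    "read_units",
    "read_kinship",
    "build_presence",
    "filter_min_visits",
    "split_periods",
]


class FormatError(ValueError):
    """Raised when an input file does not conform to the expected layout."""


@dataclass(frozen=True)
class VisitRecord:
    """One unit-day attendance event, at day resolution."""

    unit_id: str
    day: int


@dataclass(frozen=True)
class UnitInfo:
    """Static description of one social unit (network node)."""

    unit_id: str
    kind: str  # "group" or "solitary"
    n_individuals: int
    silverback_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("group", "solitary"):
            raise ValueError(f"unit {self.unit_id}: kind must be 'group' or 'solitary'")
        if self.n_individuals < 1:
            raise ValueError(f"unit {self.unit_id}: n_individuals must be >= 1")
        if self.kind == "solitary" and self.n_individuals != 1:
            raise ValueError(f"solitary unit {self.unit_id} must have n_individuals == 1")


@dataclass(frozen=True)
class StudyPeriod:
    """A closed interval of day indices, e.g. one 2-year dataset."""

    label: str
    start_day: int
    end_day: int

    def __post_init__(self) -> None:
        if self.end_day < self.start_day:
            raise ValueError(f"period {self.label}: end_day < start_day")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    def contains(self, day: int) -> bool:
        return self.start_day <= day <= self.end_day

    @classmethod
    def from_dates(
        cls,
        label: str,
        start: _dt.date,
        end: _dt.date,
        origin: _dt.date,
    ) -> "StudyPeriod":
        """Build a period from calendar dates relative to an origin date."""
        return cls(label, (start - origin).days, (end - origin).days)


@dataclass
class PresenceMatrix:
    """Binary units x days attendance matrix.

    Row sums are per-unit visit counts v_i; column sums are daily attendance;
    the inner product of rows i and j is the covisit count k_ij.  Days with
    zero attendance are kept as columns: the number of observation days T is
    the study length, not the number of attended days.
    """

    units: list[str]
    days: np.ndarray  # day indices, shape (T,)
    X: np.ndarray  # uint8 {0,1}, shape (n_units, T)

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=np.uint8)
        if self.X.shape != (len(self.units), len(self.days)):
            raise ValueError("presence matrix shape does not match units/days")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("presence cells must be binary")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def T(self) -> int:
        return len(self.days)

    def visit_counts(self) -> np.ndarray:
        """Per-unit visit counts v_i (row sums)."""
        return self.X.sum(axis=1).astype(np.int64)

    def attendance(self) -> np.ndarray:
        """Per-day number of units present (column sums)."""
        return self.X.sum(axis=0).astype(np.int64)

    def covisits(self) -> np.ndarray:
        """Pairwise covisit counts k_ij = days both units attended."""
        Xi = self.X.astype(np.int64)
        return Xi @ Xi.T

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.units, columns=self.days)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="unit_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, index_col="unit_id")
        return cls(
            units=[str(u) for u in df.index],
            days=df.columns.astype(np.int64).to_numpy(),
            X=df.to_numpy(),
        )


def _parse_dates(raw: pd.Series, path: str | Path) -> tuple[np.ndarray, _dt.date | None]:
    """Return integer day offsets plus the origin date (None for integer input)."""
    as_num = pd.to_numeric(raw, errors="coerce")
    if as_num.notna().all():
        if not (as_num == as_num.round()).all():
            bad = int(as_num.index[as_num != as_num.round()][0]) + 2
            raise FormatError(f"{path}: non-integer day index at line {bad}")
        return as_num.astype(np.int64).to_numpy(), None
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = int(parsed.index[parsed.isna()][0]) + 2  # +1 header, +1 one-based
        raise FormatError(f"{path}: unparseable date {raw[parsed.isna()].iloc[0]!r} at line {bad}")
    origin = parsed.min().date()
    days = (parsed - parsed.min()).dt.days.astype(np.int64).to_numpy()
    return days, origin


def read_visits(path: str | Path) -> list[VisitRecord]:
    """Read a visits CSV with columns ``unit_id,date``.

    Dates may be ISO-8601 calendar dates (converted to 0-based day indices
    relative to the earliest date in the file) or already-integer day indices.
    Duplicate (unit, day) rows collapse to a single record; output is sorted
    by (day, unit_id).
    """
    df = pd.read_csv(path, dtype={"unit_id": str})
    for col in ("unit_id", "date"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if df.empty:
        return []
    days, _origin = _parse_dates(df["date"], path)
    pairs = {(str(u), int(d)) for u, d in zip(df["unit_id"], days)}
    n_dup = len(df) - len(pairs)
    if n_dup:
        log.info("read_visits(%s): collapsed %d duplicate unit-day rows", path, n_dup)
    return [VisitRecord(u, d) for d, u in sorted((d, u) for u, d in pairs)]


def write_visits(records: Iterable[VisitRecord], path: str | Path) -> None:
    recs = sorted({(r.day, r.unit_id) for r in records})
    pd.DataFrame(
        {"unit_id": [u for _, u in recs], "date": [d for d, _ in recs]}
    ).to_csv(path, index=False)


def read_units(path: str | Path) -> dict[str, UnitInfo]:
    """Read unit metadata CSV ``unit_id,kind,n_individuals,silverback_id``."""
    df = pd.read_csv(path, dtype={"unit_id": str, "silverback_id": str})
    for col in ("unit_id", "kind", "n_individuals"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out: dict[str, UnitInfo] = {}
    for row in df.itertuples(index=False):
        sb = getattr(row, "silverback_id", None)
        if sb is not None and pd.isna(sb):
            sb = None
        out[str(row.unit_id)] = UnitInfo(
            str(row.unit_id), str(row.kind), int(row.n_individuals), sb
        )
    return out


def read_kinship(path: str | Path) -> pd.DataFrame:
    """Read pairwise binary kinship CSV ``silverback_a,silverback_b,related``."""
    df = pd.read_csv(path, dtype={"silverback_a": str, "silverback_b": str})
    for col in ("silverback_a", "silverback_b", "related"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if not df["related"].isin((0, 1)).all():
        raise FormatError(f"{path}: 'related' must be binary 0/1")
    return df


def build_presence(records: Sequence[VisitRecord], period: StudyPeriod) -> PresenceMatrix:
    """Assemble the binary presence matrix for one study period.

    Columns span every day of the period; rows are the distinct units with at
    least one record in the period, in sorted order.
    """
    for r in records:
        if not period.contains(r.day):
            raise ValueError(
                f"record ({r.unit_id}, day {r.day}) outside period "
                f"{period.label} [{period.start_day}, {period.end_day}]"
            )
    units = sorted({r.unit_id for r in records})
    idx = {u: i for i, u in enumerate(units)}
    X = np.zeros((len(units), period.n_days), dtype=np.uint8)
    for r in records:
        X[idx[r.unit_id], r.day - period.start_day] = 1
    return PresenceMatrix(units, period.start_day + np.arange(period.n_days), X)


def filter_min_visits(pm: PresenceMatrix, min_visits: int = 8) -> PresenceMatrix:
    """Drop units seen fewer than ``min_visits`` times; keep all day columns."""
    if min_visits < 0:
        raise ValueError("min_visits must be >= 0")
    keep = pm.visit_counts() >= min_visits
    if not keep.any():
        raise ValueError(
            f"all units have < {min_visits} visits; lower the threshold"
        )
    units = [u for u, k in zip(pm.units, keep) if k]
    return PresenceMatrix(units, pm.days.copy(), pm.X[keep].copy())


def split_periods(
    records: Sequence[VisitRecord], periods: Sequence[StudyPeriod]
) -> list[tuple[StudyPeriod, PresenceMatrix]]:
    """Split records into consecutive study periods and build one matrix each.

    Periods must be ordered and non-overlapping (closed day intervals).
    Records outside every period are dropped with a logged count.
    """
    for a, b in zip(periods, periods[1:]):
        if b.start_day <= a.end_day:
            raise ValueError(f"periods {a.label} and {b.label} overlap or are unordered")
    out = []
    n_used = 0
    for p in periods:
        sub = [r for r in records if p.contains(r.day)]
        n_used += len(sub)
        out.append((p, build_presence(sub, p)))
    n_dropped = len(records) - n_used
    if n_dropped:
        log.info("split_periods: %d records fell outside all periods", n_dropped)
    return out
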