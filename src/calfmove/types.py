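"""Shared domain types: pen geometry, rosters, coverage accounting.

Trajectories and metric panels are plain :class:`pandas.DataFrame` objects
with documented column contracts (see :data:`TRAJECTORY_COLUMNS` and
:data:`METRIC_COLUMNS`); only the small structured records get dataclasses.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Required columns of a trajectory table, one row per (calf, sample).
TRAJECTORY_COLUMNS = ("calf_id", "t", "x", "y")

#: Columns of the daily metric panel consumed by the model layer.
METRIC_COLUMNS = (
    "calf_id",
    "date",
    "metric_name",
    "value",
    "day_of_observation",
    "age",
    "housing",
    "health",
    "cohort_id",
)

HEALTH_LEVELS = ("healthy", "sick", "convalescent")
HOUSING_LEVELS = ("pair", "group")


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (not banker's rounding)."""
    q = decimal.Decimal(1).scaleb(-ndigits)
    d = decimal.Decimal(repr(float(value))).quantize(
        q, rounding=decimal.ROUND_HALF_UP
    )
    return float(d)


@dataclass(frozen=True)
class PenGeometry:
    """Axis-aligned rectangular pen in a local metric frame."""

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    label: str = "pair"

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError("x_max must exceed x_min")
        if not self.y_max > self.y_min:
            raise ValueError("y_max must exceed y_min")
        if self.label not in HOUSING_LEVELS:
            raise ValueError(f"label must be one of {HOUSING_LEVELS}")

    @classmethod
    def pair_default(cls) -> "PenGeometry":
        return cls(0.0, 1.5, 0.0, 3.5, "pair")

    @classmethod
    def group_default(cls) -> "PenGeometry":
        return cls(0.0, 6.0, 0.0, 10.0, "group")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    def area_per_occupant(self, n_occupants: int, ndigits: int | None = None) -> float:
        """Floor area available per animal, optionally rounded half-up."""
        if n_occupants <= 0:
            raise ValueError("n_occupants must be positive")
        value = self.area / n_occupants
        if ndigits is not None:
            value = round_half_up(value, ndigits)
        return value

    def contains(self, x, y) -> np.ndarray:
        """Vectorised point-in-pen test; boundary points count as inside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min)
            & (x <= self.x_max)
            & (y >= self.y_min)
            & (y <= self.y_max)
        )


@dataclass(frozen=True)
class ExclusionIntervals:
    """Half-open time intervals ``[start, end)`` to drop from trajectories.

    Intervals may overlap; union semantics apply.
    """

    intervals: tuple[tuple[float, float, str], ...] = ()

    def __post_init__(self) -> None:
        for start, end, _reason in self.intervals:
            if not end > start:
                raise ValueError(f"interval end {end} must exceed start {start}")

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[float, float, str]]
    ) -> "ExclusionIntervals":
        return cls(tuple((float(s), float(e), str(r)) for s, e, r in records))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExclusionIntervals":
        return cls.from_records(
            list(df[["start", "end", "reason"]].itertuples(index=False, name=None))
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["start", "end", "reason"])

    def contains_times(self, t: np.ndarray) -> np.ndarray:
        """Boolean mask of times falling in the union of intervals."""
        t = np.asarray(t, dtype=float)
        mask = np.zeros(t.shape, dtype=bool)
        for start, end, _ in self.intervals:
            mask |= (t >= start) & (t < end)
        return mask


@dataclass
class CoverageReport:
    """Accounting of how much recording was removed during cleaning."""

    total_calf_hours: float
    removed_calf_hours: float
    out_of_pen_points_removed: int = 0

    def __post_init__(self) -> None:
        if self.total_calf_hours < 0 or self.removed_calf_hours < 0:
            raise ValueError("calf-hours must be non-negative")
        if self.removed_calf_hours > self.total_calf_hours + 1e-9:
            raise ValueError("removed calf-hours cannot exceed the total")

    @property
    def removed_fraction(self) -> float:
        if self.total_calf_hours == 0:
            return 0.0
        return self.removed_calf_hours / self.total_calf_hours

    def removed_percent(self, ndigits: int = 1) -> float:
        """Removed share as a percentage, rounded half-up."""
        return round_half_up(100.0 * self.removed_fraction, ndigits)

    def formatted(self) -> str:
        return (
            f"{self.removed_calf_hours:g} of {self.total_calf_hours:g} calf-hours "
            f"removed ({self.removed_percent():.1f}%); "
            f"{self.out_of_pen_points_removed} out-of-pen points dropped"
        )


@dataclass
class Roster:
    """Cohort membership, pen pairs, ages and daily health labels.

    ``calves`` has one row per calf with columns
    ``calf_id, cohort_id, pair_id, age_at_group_day0``; ``health`` has one
    row per calf-day with columns ``calf_id, day, health``.
    """

    calves: pd.DataFrame
    health: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"calf_id", "cohort_id", "pair_id", "age_at_group_day0"}
        missing = required - set(self.calves.columns)
        if missing:
            raise ValueError(f"roster missing columns: {sorted(missing)}")
        if self.calves["calf_id"].duplicated().any():
            raise ValueError("duplicate calf_id in roster")
        sizes = self.calves.groupby("pair_id")["calf_id"].nunique()
        if (sizes != 2).any():
            bad = sizes[sizes != 2].index.tolist()
            raise ValueError(f"pair_ids not mapping to exactly 2 calves: {bad}")
        ncoh = self.calves.groupby("pair_id")["cohort_id"].nunique()
        if (ncoh != 1).any():
            raise ValueError("pairs must lie within a single cohort")
        if len(self.health):
            bad = set(self.health["health"]) - set(HEALTH_LEVELS)
            if bad:
                raise ValueError(f"unknown health labels: {sorted(bad)}")

    @property
    def calf_ids(self) -> list:
        return self.calves["calf_id"].tolist()

    @property
    def n_calves(self) -> int:
        return len(self.calves)

    def pair_of(self) -> dict:
        """Map calf_id -> pen-mate calf_id."""
        out = {}
        for _, grp in self.calves.groupby("pair_id"):
            a, b = grp["calf_id"].tolist()
            out[a] = b
            out[b] = a
        return out

    def health_on(self, calf_id, day: int) -> str:
        if not len(self.health):
            return "healthy"
        rows = self.health[
            (self.health["calf_id"] == calf_id) & (self.health["day"] == day)
        ]
        return "healthy" if rows.empty else str(rows["health"].iloc[0])


def validate_trajectory(traj: pd.DataFrame) -> None:
    """Check the trajectory column contract and per-calf time ordering."""
    missing = set(TRAJECTORY_COLUMNS) - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory missing columns: {sorted(missing)}")
    if not np.isfinite(traj[["t", "x", "y"]].to_numpy(dtype=float)).all():
        raise ValueError("trajectory contains non-finite values")
    for calf, grp in traj.groupby("calf_id"):
        dt = np.diff(grp["t"].to_numpy(dtype=float))
        if len(dt) and (dt <= 0).any():
            raise ValueError(f"timestamps not strictly increasing for calf {calf}")
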