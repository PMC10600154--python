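"""Movement metrics (daily distance travelled, residence time) and static
sensor validation statistics (CEP, DIST)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Roster, validate_trajectory

__all__ = [
    "StaticTagTest",
    "daily_distance",
    "residence_time_at",
    "daily_residence_time",
    "cep",
    "dist_accuracy",
    "attach_covariates",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StaticTagTest:
    """Readings of a tag fixed at a known position."""

    truth: tuple[float, float]
    readings: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        readings = np.asarray(self.readings, dtype=float)
        if readings.ndim != 2 or readings.shape[1] != 2:
            raise ValueError("readings must have shape (n, 2)")
        object.__setattr__(self, "readings", readings)


def cep(test: StaticTagTest) -> float:
    """Circular error probability: the smallest radius around the *mean*
    reading containing at least half of the readings.

    Equals the ceil(n/2)-th smallest distance to the mean.
    """
    r = test.readings
    if len(r) < 2:
        raise ValueError("CEP needs at least 2 readings")
    centre = r.mean(axis=0)
    d = np.sort(np.hypot(r[:, 0] - centre[0], r[:, 1] - centre[1]))
    k = math.ceil(len(d) / 2)
    return float(d[k - 1])


def dist_accuracy(test: StaticTagTest) -> float:
    """Mean Euclidean distance between ground truth and each reading."""
    r = test.readings
    if len(r) < 1:
        raise ValueError("DIST needs at least 1 reading")
    return float(np.hypot(r[:, 0] - test.truth[0], r[:, 1] - test.truth[1]).mean())


def _day_index(t: np.ndarray, day_length: float, day_origin: float) -> np.ndarray:
    return np.floor((t - day_origin) / day_length).astype(int)


def daily_distance(
    traj: pd.DataFrame,
    day_length: float = 86400.0,
    day_origin: float = 0.0,
    gap_threshold: float = 60.0,
) -> pd.DataFrame:
    """Per calf-day sum of Euclidean distances between consecutive samples.

    A segment belongs to the day of its leading sample; segments spanning
    a time gap longer than ``gap_threshold`` seconds contribute zero (they
    straddle an exclusion hole and would create phantom displacement).
    Days with fewer than 2 samples are omitted and logged.
    """
    validate_trajectory(traj)
    rows = []
    for calf, grp in traj.groupby("calf_id", sort=True):
        t = grp["t"].to_numpy(float)
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        day = _day_index(t, day_length, day_origin)
        seg = np.hypot(np.diff(x), np.diff(y))
        seg[np.diff(t) > gap_threshold] = 0.0
        seg_day = day[:-1]  # leading sample's day
        for d in np.unique(day):
            n_samples = int((day == d).sum())
            if n_samples < 2:
                logger.info(
                    "calf %s day %d has %d sample(s); distance row omitted",
                    calf, d, n_samples,
                )
                continue
            rows.append((calf, int(d), "distance", float(seg[seg_day == d].sum())))
    return pd.DataFrame(rows, columns=["calf_id", "date", "metric_name", "value"])


def residence_time_at(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    i: int,
    radius: float = 1.0,
    max_gap: float = 60.0,
) -> float:
    """Residence time at sample ``i``: duration spent inside the circle of
    ``radius`` centred on position ``i``, tolerating excursions of at most
    ``max_gap`` seconds, scanning both backward and forward.

    Returns ``t_fwd - t_bwd`` where ``t_fwd`` (``t_bwd``) is the time of
    the last (first) inside sample reachable from ``i`` through a chain of
    inside samples whose consecutive time gaps never exceed ``max_gap``.
    """
    n = len(t)
    if not 0 <= i < n:
        raise IndexError(f"sample index {i} out of range [0, {n})")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    d = np.hypot(x - x[i], y - y[i])
    inside_idx = np.flatnonzero(d <= radius)
    ts_in = t[inside_idx]
    pos = int(np.searchsorted(inside_idx, i))
    # forward chain
    fwd = ts_in[pos:]
    gaps = np.diff(fwd)
    bad = gaps > max_gap
    k = int(np.argmax(bad)) if bad.any() else len(gaps)
    t_fwd = fwd[k]
    # backward chain (mirror)
    bwd = ts_in[: pos + 1][::-1]
    gaps = -np.diff(bwd)
    bad = gaps > max_gap
    k = int(np.argmax(bad)) if bad.any() else len(gaps)
    t_bwd = bwd[k]
    return float(t_fwd - t_bwd)


def daily_residence_time(
    traj: pd.DataFrame,
    day_length: float = 86400.0,
    day_origin: float = 0.0,
    radius: float = 1.0,
    max_gap: float = 60.0,
    stride: int = 10,
) -> pd.DataFrame:
    """Per calf-day mean of per-sample residence times.

    ``stride`` subsamples the centre indices for tractability (stride 1 is
    the exact reference).  Residence is evaluated within the day's track.
    Empty days are omitted and logged.
    """
    validate_trajectory(traj)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = []
    for calf, grp in traj.groupby("calf_id", sort=True):
        t = grp["t"].to_numpy(float)
        x = grp["x"].to_numpy(float)
        y = grp["y"].to_numpy(float)
        day = _day_index(t, day_length, day_origin)
        for d in np.unique(day):
            sel = day == d
            td, xd, yd = t[sel], x[sel], y[sel]
            if len(td) == 0:
                logger.info("calf %s day %d empty; residence row omitted", calf, d)
                continue
            centres = range(0, len(td), stride)
            vals = [
                residence_time_at(td, xd, yd, i, radius=radius, max_gap=max_gap)
                for i in centres
            ]
            rows.append((calf, int(d), "residence_time", float(np.mean(vals))))
    return pd.DataFrame(rows, columns=["calf_id", "date", "metric_name", "value"])


def attach_covariates(
    metric_rows: pd.DataFrame,
    roster: Roster,
    days_per_housing: int,
) -> pd.DataFrame:
    """Join roster covariates onto metric rows to form the model panel.

    Dates ``0 .. days_per_housing - 1`` are pair housing, later dates group
    housing; ``day_of_observation`` runs continuously from 1.
    """
    calves = roster.calves.set_index("calf_id")
    out = metric_rows.copy()
    out["day_of_observation"] = out["date"].astype(float) + 1.0
    out["age"] = out["calf_id"].map(calves["age_at_group_day0"]).astype(float)
    out["housing"] = np.where(out["date"] < days_per_housing, "pair", "group")
    out["cohort_id"] = out["calf_id"].map(calves["cohort_id"])
    if len(roster.health):
        key = roster.health.set_index(["calf_id", "day"])["health"]
        idx = pd.MultiIndex.from_frame(out[["calf_id", "date"]])
        out["health"] = key.reindex(idx).fillna("healthy").to_numpy()
    else:
        out["health"] = "healthy"
    return out[
        [
            "calf_id",
            "date",
            "metric_name",
            "value",
            "day_of_observation",
            "age",
            "housing",
            "health",
            "cohort_id",
        ]
    ]
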