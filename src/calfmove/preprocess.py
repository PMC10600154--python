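"""Positional data cleaning: exclusion intervals, out-of-pen filtering,
moving-average smoothing, and coverage accounting.

The pipeline order is fixed: exclusions first, then the out-of-pen filter,
then smoothing on the retained raw points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import CoverageReport, ExclusionIntervals, PenGeometry, validate_trajectory

__all__ = [
    "apply_exclusions",
    "filter_out_of_pen",
    "smooth_moving_average",
    "run_preprocess",
]


def apply_exclusions(
    traj: pd.DataFrame, intervals: ExclusionIntervals, hz: float = 1.0
) -> tuple[pd.DataFrame, CoverageReport]:
    """Drop samples whose time falls in the union of [start, end) intervals.

    The returned report accounts total and removed calf-hours as
    sample counts divided by ``hz`` and 3600.
    """
    validate_trajectory(traj)
    t = traj["t"].to_numpy(dtype=float)
    mask = intervals.contains_times(t)
    kept = traj.loc[~mask].reset_index(drop=True)
    total_h = len(traj) / hz / 3600.0
    removed_h = int(mask.sum()) / hz / 3600.0
    return kept, CoverageReport(total_calf_hours=total_h, removed_calf_hours=removed_h)


def filter_out_of_pen(
    traj: pd.DataFrame, pen: PenGeometry
) -> tuple[pd.DataFrame, int]:
    """Drop samples outside the pen rectangle; boundary points are kept."""
    validate_trajectory(traj)
    inside = pen.contains(traj["x"].to_numpy(float), traj["y"].to_numpy(float))
    kept = traj.loc[inside].reset_index(drop=True)
    return kept, int((~inside).sum())


def smooth_moving_average(traj: pd.DataFrame, window_s: float = 10.0) -> pd.DataFrame:
    """Centred time-based moving average of x and y per calf.

    A sample at time ``t_i`` is replaced by the mean over samples with
    ``|t_j - t_i| <= window_s / 2``.  Windows truncate at record edges and
    across gaps: only the samples present are averaged, so row count is
    preserved and no interpolation happens.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    validate_trajectory(traj)
    half = window_s / 2.0
    out = []
    for _, grp in traj.groupby("calf_id", sort=False):
        t = grp["t"].to_numpy(dtype=float)
        lo = np.searchsorted(t, t - half, side="left")
        hi = np.searchsorted(t, t + half, side="right")
        cs_x = np.concatenate(([0.0], np.cumsum(grp["x"].to_numpy(float))))
        cs_y = np.concatenate(([0.0], np.cumsum(grp["y"].to_numpy(float))))
        cnt = hi - lo
        sm = grp.copy()
        sm["x"] = (cs_x[hi] - cs_x[lo]) / cnt
        sm["y"] = (cs_y[hi] - cs_y[lo]) / cnt
        out.append(sm)
    result = pd.concat(out, ignore_index=True)
    result["quality_flag"] = "smoothed"
    return result


def run_preprocess(
    traj: pd.DataFrame,
    intervals: ExclusionIntervals,
    pen: PenGeometry,
    window_s: float = 10.0,
    hz: float = 1.0,
) -> tuple[pd.DataFrame, CoverageReport]:
    """Full cleaning pass: exclusions -> out-of-pen filter -> smoothing."""
    kept, report = apply_exclusions(traj, intervals, hz=hz)
    kept, n_out = filter_out_of_pen(kept, pen)
    report.out_of_pen_points_removed = n_out
    if len(kept) == 0:
        empty = kept.copy()
        empty["quality_flag"] = pd.Series(dtype=object)
        return empty, report
    smoothed = smooth_moving_average(kept, window_s=window_s)
    return smoothed, report
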