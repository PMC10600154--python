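"""Pen-mate similarity: CV of absolute pen-mate intercept differences and
its permutation test.

The statistic is the coefficient of variation of ``|intercept_a -
intercept_b|`` over pen pairs.  Under the test's null, calf identities are
randomly re-assigned to the fixed pair structure (within cohort by
default) and the CV recomputed; with ``direction='lower'`` a small p-value
means pen-mates are *less* variable in their difference than random pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .types import Roster

__all__ = ["PermutationResult", "penmate_cv", "permutation_test"]


@dataclass
class PermutationResult:
    observed_cv: float
    null_cvs: np.ndarray
    p_value: float
    B: int
    seed: int | None
    direction: str

    def summary_row(self) -> dict:
        return {
            "observed_cv": self.observed_cv,
            "p_value": self.p_value,
            "B": self.B,
            "seed": self.seed,
            "direction": self.direction,
        }


def _pair_arrays(intercepts: Mapping, roster: Roster):
    """Return (values, cohort_codes, pair_index) aligned arrays.

    ``pair_index`j`` holds, for each calf slot, which pair it belongs to;
    slots are ordered so consecutive entries within a pair are adjacent.
    """
    calves = roster.calves.sort_values(["cohort_id", "pair_id", "calf_id"])
    missing = [c for c in calves["calf_id"] if c not in intercepts]
    if missing:
        raise ValueError(f"calves without an intercept value: {missing}")
    vals = np.array([float(intercepts[c]) for c in calves["calf_id"]])
    coh = pd.Categorical(calves["cohort_id"]).codes
    pair = pd.Categorical(calves["pair_id"]).codes
    return vals, np.asarray(coh), np.asarray(pair)


def _cv_of_absdiff(vals: np.ndarray, pair: np.ndarray) -> float:
    order = np.argsort(pair, kind="stable")
    v = vals[order].reshape(-1, 2)
    d = np.abs(v[:, 0] - v[:, 1])
    m = d.mean()
    if m == 0:
        return 0.0
    return float(d.std(ddof=1) / m)


def penmate_cv(intercepts: Mapping, roster: Roster) -> float:
    """CV (sample sd / mean) of absolute pen-mate intercept differences.

    Returns 0 by convention when the mean difference is 0.
    """
    vals, _, pair = _pair_arrays(intercepts, roster)
    return _cv_of_absdiff(vals, pair)


def permutation_test(
    intercepts: Mapping,
    roster: Roster,
    B: int = 10_000,
    seed: int | None = None,
    direction: str = "lower",
    within_cohort: bool = True,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation test of pen-mate similarity.

    Calf identities are shuffled (within cohort unless ``within_cohort``
    is False) onto the fixed pair structure B times.  ``direction='lower'``
    gives ``p = #(observed <= null) / B`` (small p: pen-mates more similar
    than chance); ``'upper'`` the opposite tail.  ``add_one`` applies the
    (k+1)/(B+1) correction, which guarantees p > 0 and is recommended.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if direction not in ("lower", "upper"):
        raise ValueError("direction must be 'lower' or 'upper'")
    vals, coh, pair = _pair_arrays(intercepts, roster)
    observed = _cv_of_absdiff(vals, pair)
    rng = np.random.default_rng(seed)
    null_cvs = np.empty(B)
    perm = np.arange(len(vals))
    groups = (
        [np.flatnonzero(coh == k) for k in np.unique(coh)]
        if within_cohort
        else [np.arange(len(vals))]
    )
    for b in range(B):
        for idx in groups:
            perm[idx] = idx[rng.permutation(len(idx))]
        null_cvs[b] = _cv_of_absdiff(vals[perm], pair)
    if direction == "lower":
        k = int((observed <= null_cvs).sum())
    else:
        k = int((observed >= null_cvs).sum())
    p = (k + 1) / (B + 1) if add_one else k / B
    return PermutationResult(
        observed_cv=observed,
        null_cvs=null_cvs,
        p_value=float(p),
        B=B,
        seed=seed,
        direction=direction,
    )
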