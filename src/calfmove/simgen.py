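"""Synthetic data generation with known ground truth.

Two levels of generation are provided:

* :func:`simulate_metric_panel` draws daily metric values directly from the
  random-slope mixed-model structure (cohort intercepts, correlated
  individual intercepts/slopes, fixed effects, residual noise), plus an
  optional pen-mate conformity blend in pair housing.
* :func:`simulate_trajectories` draws 1 Hz positional tracks from a
  two-state (rest/move) switching process inside a rectangular pen, with
  additive isotropic Gaussian sensor noise.

Both return the generating truth alongside the data so downstream
estimators can be tested by parameter recovery, with no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .types import PenGeometry, Roster

__all__ = [
    "FixedEffects",
    "MetricSimConfig",
    "TrajectorySimConfig",
    "SimTruth",
    "make_roster",
    "simulate_metric_panel",
    "simulate_trajectories",
]


@dataclass(frozen=True)
class FixedEffects:
    """Fixed-effect coefficients of the generating model.

    The housing default (496.2, metric units per unit housing contrast) is
    data-derived from published results and serves as a display-scale
    anchor, not ground truth.  Health coefficients apply to the two
    non-healthy levels relative to healthy.
    """

    intercept: float = 2000.0
    day: float = 5.0
    age: float = 10.0
    housing: float = 496.2  # data-derived default, group minus pair
    health_sick: float = -150.0
    health_convalescent: float = -75.0


@dataclass(frozen=True)
class MetricSimConfig:
    n_cohorts: int = 6
    calves_per_cohort: int = 16
    days_per_housing: int = 20
    fixed_effects: FixedEffects = field(default_factory=FixedEffects)
    var_cohort: float = 10_000.0
    var_ind_intercept: float = 62_500.0
    var_ind_slope: float = 40_000.0
    cor_intercept_slope: float = 0.57  # data-derived default
    var_resid: float = 187_500.0
    conformity_weight: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("var_cohort", "var_ind_intercept", "var_ind_slope", "var_resid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.cor_intercept_slope) > 1:
            raise ValueError("|cor_intercept_slope| must be <= 1")
        if not 0.0 <= self.conformity_weight <= 1.0:
            raise ValueError("conformity_weight must lie in [0, 1]")
        # PSD check of the implied 2x2 individual covariance.
        cov = self.individual_covariance()
        if np.linalg.eigvalsh(cov).min() < -1e-12:
            raise ValueError("individual covariance is not positive semidefinite")

    def individual_covariance(self) -> np.ndarray:
        c = self.cor_intercept_slope * math.sqrt(
            self.var_ind_intercept * self.var_ind_slope
        )
        return np.array(
            [[self.var_ind_intercept, c], [c, self.var_ind_slope]], dtype=float
        )


@dataclass(frozen=True)
class TrajectorySimConfig:
    pen: PenGeometry = field(default_factory=PenGeometry.group_default)
    hz: float = 1.0
    rest_to_move_rate: float = 0.02  # per second
    move_to_rest_rate: float = 0.05
    move_speed: float = 0.5  # m/s
    attraction_points: tuple[tuple[float, float], ...] = ()
    sensor_noise_sd: float = 0.15
    duration: float = 3600.0
    heading_jitter_sd: float = 0.3  # radians per step while moving
    start_moving: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rest_to_move_rate <= 0 or self.move_to_rest_rate <= 0:
            raise ValueError("switching rates must be > 0")
        if self.sensor_noise_sd < 0:
            raise ValueError("sensor_noise_sd must be >= 0")
        if self.hz <= 0 or self.duration <= 0:
            raise ValueError("hz and duration must be > 0")
        for x, y in self.points():
            if not self.pen.contains(x, y):
                raise ValueError(f"attraction point ({x}, {y}) lies outside the pen")

    def points(self) -> tuple[tuple[float, float], ...]:
        if self.attraction_points:
            return self.attraction_points
        p = self.pen
        cx, cy = (p.x_min + p.x_max) / 2, (p.y_min + p.y_max) / 2
        w, h = p.x_max - p.x_min, p.y_max - p.y_min
        # feeder, trough, lying area analogues at fixed relative spots
        return (
            (p.x_min + 0.1 * w, p.y_min + 0.1 * h),
            (p.x_max - 0.1 * w, p.y_min + 0.1 * h),
            (cx, p.y_max - 0.15 * h),
        )


@dataclass
class SimTruth:
    """Ground-truth draws of a metric-level simulation."""

    calf_effects: pd.DataFrame  # calf_id, b0, b1, b0_pair_effective
    cohort_effects: pd.DataFrame  # cohort_id, effect
    config: MetricSimConfig

    def to_frames(self) -> dict[str, pd.DataFrame]:
        cfg = asdict(self.config)
        fe = cfg.pop("fixed_effects")
        cfg.update({f"fixed_{k}": v for k, v in fe.items()})
        return {
            "calf_effects": self.calf_effects,
            "cohort_effects": self.cohort_effects,
            "config": pd.DataFrame([cfg]),
        }


def make_roster(
    n_cohorts: int,
    calves_per_cohort: int,
    seed: int,
    *,
    n_days: int = 40,
    age_mean: float = 36.6,
    age_sd: float = 4.0,
    sick_hazard: float = 0.01,
    sick_days: int = 3,
    convalescent_days: int = 3,
) -> Roster:
    """Build a synthetic cohort/pair roster with ages and health episodes.

    Ages are normal(age_mean, age_sd) truncated at zero; health follows a
    daily hazard of falling sick, then a fixed sick + convalescent episode.
    """
    if calves_per_cohort % 2 != 0:
        raise ValueError(
            f"calves_per_cohort must be even so pairs tile the cohort; "
            f"got {calves_per_cohort}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    health_rows = []
    for k in range(n_cohorts):
        cohort_id = f"coh{k + 1}"
        for j in range(calves_per_cohort):
            calf_id = f"{cohort_id}_c{j + 1:02d}"
            pair_id = f"{cohort_id}_p{j // 2 + 1}"
            age = 0.0
            while age <= 0.0:
                age = rng.normal(age_mean, age_sd)
            rows.append((calf_id, cohort_id, pair_id, float(age)))
            # hazard-driven health episodes
            state, remaining = "healthy", 0
            for day in range(n_days):
                if state == "healthy":
                    if rng.random() < sick_hazard:
                        state, remaining = "sick", sick_days
                elif remaining == 0:
                    if state == "sick":
                        state, remaining = "convalescent", convalescent_days
                    else:
                        state = "healthy"
                if state != "healthy":
                    remaining -= 1
                health_rows.append((calf_id, day, state))
    calves = pd.DataFrame(
        rows, columns=["calf_id", "cohort_id", "pair_id", "age_at_group_day0"]
    )
    health = pd.DataFrame(health_rows, columns=["calf_id", "day", "health"])
    return Roster(calves=calves, health=health)


def simulate_metric_panel(
    roster: Roster, cfg: MetricSimConfig, metric_name: str = "distance"
) -> tuple[pd.DataFrame, SimTruth]:
    """Draw a calf-day metric panel from the random-slope model structure.

    Each calf contributes ``2 * days_per_housing`` rows: the first block in
    pair housing, the second in group housing.  In pair housing the
    individual intercept is blended toward the pair mean with weight
    ``conformity_weight``; group housing always uses the calf's own draw.
    """
    calves = roster.calves
    expected = cfg.n_cohorts * cfg.calves_per_cohort
    if len(calves) != expected:
        raise ValueError(
            f"roster has {len(calves)} calves but config implies {expected}"
        )
    rng = np.random.default_rng(cfg.seed)
    fe = cfg.fixed_effects

    cohort_ids = sorted(calves["cohort_id"].unique())
    coh_eff = rng.normal(0.0, math.sqrt(cfg.var_cohort), size=len(cohort_ids))
    coh_map = dict(zip(cohort_ids, coh_eff))

    cov = cfg.individual_covariance()
    # sqrtm via eigendecomposition keeps zero-variance configs exact
    evals, evecs = np.linalg.eigh(cov)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None))) @ evecs.T
    z = rng.standard_normal((len(calves), 2))
    b = z @ root.T  # columns: intercept dev b0, slope dev b1

    eff = calves[["calf_id", "cohort_id", "pair_id"]].copy()
    eff["b0"] = b[:, 0]
    eff["b1"] = b[:, 1]
    pair_mean = eff.groupby("pair_id")["b0"].transform("mean")
    w = cfg.conformity_weight
    eff["b0_pair_effective"] = (1.0 - w) * eff["b0"] + w * pair_mean

    n_days_total = 2 * cfg.days_per_housing
    health_coef = {
        "healthy": 0.0,
        "sick": fe.health_sick,
        "convalescent": fe.health_convalescent,
    }
    health_lookup: dict[tuple, str] = {}
    if len(roster.health):
        health_lookup = {
            (r.calf_id, r.day): r.health for r in roster.health.itertuples()
        }

    rows = []
    for rec in eff.itertuples():
        age = float(
            calves.loc[calves["calf_id"] == rec.calf_id, "age_at_group_day0"].iloc[0]
        )
        coh = coh_map[rec.cohort_id]
        resid = rng.normal(0.0, math.sqrt(cfg.var_resid), size=n_days_total)
        for d in range(n_days_total):
            housing = "pair" if d < cfg.days_per_housing else "group"
            hz01 = 0.0 if housing == "pair" else 1.0
            b0_eff = rec.b0_pair_effective if housing == "pair" else rec.b0
            health = health_lookup.get((rec.calf_id, d), "healthy")
            value = (
                fe.intercept
                + coh
                + b0_eff
                + (fe.housing + rec.b1) * hz01
                + fe.day * (d + 1)
                + fe.age * age
                + health_coef[health]
                + resid[d]
            )
            rows.append(
                (
                    rec.calf_id,
                    d,
                    metric_name,
                    value,
                    float(d + 1),
                    age,
                    housing,
                    health,
                    rec.cohort_id,
                )
            )
    panel = pd.DataFrame(
        rows,
        columns=[
            "calf_id",
            "date",
            "metric_name",
            "value",
            "day_of_observation",
            "age",
            "housing",
            "health",
            "cohort_id",
        ],
    )
    truth = SimTruth(
        calf_effects=eff[["calf_id", "cohort_id", "pair_id", "b0", "b1",
                          "b0_pair_effective"]].copy(),
        cohort_effects=pd.DataFrame(
            {"cohort_id": cohort_ids, "effect": coh_eff}
        ),
        config=cfg,
    )
    return panel, truth


def _simulate_one_track(
    cfg: TrajectorySimConfig, activity: float, rng: np.random.Generator
) -> np.ndarray:
    """Simulate one calf's true (noise-free) track; returns (n, 2) array."""
    dt = 1.0 / cfg.hz
    # samples at both endpoints: a duration-T leg yields T*hz segments
    n = int(round(cfg.duration * cfg.hz)) + 1
    points = np.asarray(cfg.points(), dtype=float)
    p_rm = -math.expm1(-cfg.rest_to_move_rate * activity * dt)
    p_mr = -math.expm1(-cfg.move_to_rest_rate * dt)
    step = cfg.move_speed * dt

    pen = cfg.pen
    pos = np.empty((n, 2))
    x = (pen.x_min + pen.x_max) / 2.0
    y = (pen.y_min + pen.y_max) / 2.0
    moving = cfg.start_moving
    target = points[0]
    for i in range(n):
        pos[i] = (x, y)
        if moving:
            if rng.random() < p_mr:
                moving = False
                continue
            dx, dy = target[0] - x, target[1] - y
            dist = math.hypot(dx, dy)
            if dist < step:
                target = points[rng.integers(len(points))]
                dx, dy = target[0] - x, target[1] - y
                dist = math.hypot(dx, dy)
                if dist == 0.0:
                    continue
            heading = math.atan2(dy, dx)
            if cfg.heading_jitter_sd > 0:
                heading += rng.normal(0.0, cfg.heading_jitter_sd)
            x += step * math.cos(heading)
            y += step * math.sin(heading)
            # walls: clip to the boundary
            x = min(max(x, pen.x_min), pen.x_max)
            y = min(max(y, pen.y_min), pen.y_max)
        else:
            if rng.random() < p_rm:
                moving = True
                target = points[rng.integers(len(points))]
    return pos


def simulate_trajectories(
    roster: Roster,
    cfg: TrajectorySimConfig,
    per_calf_activity: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate noisy tracks for every calf in the roster.

    Returns ``(observed, truth)`` trajectory frames with columns
    ``calf_id, t, x, y``: *observed* carries additive isotropic Gaussian
    sensor noise, *truth* the noise-free positions (always inside the pen).
    """
    per_calf_activity = per_calf_activity or {}
    for calf, mult in per_calf_activity.items():
        if mult <= 0:
            raise ValueError(f"activity multiplier for {calf} must be > 0")
    rng = np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.hz
    n = int(round(cfg.duration * cfg.hz)) + 1
    t = np.arange(n) * dt

    obs_frames, true_frames = [], []
    for calf_id in roster.calf_ids:
        activity = float(per_calf_activity.get(calf_id, 1.0))
        true_pos = _simulate_one_track(cfg, activity, rng)
        noise = (
            rng.normal(0.0, cfg.sensor_noise_sd, size=true_pos.shape)
            if cfg.sensor_noise_sd > 0
            else np.zeros_like(true_pos)
        )
        obs = true_pos + noise
        true_frames.append(
            pd.DataFrame(
                {"calf_id": calf_id, "t": t, "x": true_pos[:, 0], "y": true_pos[:, 1]}
            )
        )
        obs_frames.append(
            pd.DataFrame({"calf_id": calf_id, "t": t, "x": obs[:, 0], "y": obs[:, 1]})
        )
    observed = pd.concat(obs_frames, ignore_index=True)
    truth = pd.concat(true_frames, ignore_index=True)
    return observed, truth
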