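"""Plain-text serialization of the pipeline's tables and configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .simgen import FixedEffects, MetricSimConfig, TrajectorySimConfig
from .types import ExclusionIntervals, PenGeometry, Roster


def read_trajectory(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_trajectory(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False)


def read_exclusions(path: str | Path) -> ExclusionIntervals:
    return ExclusionIntervals.from_frame(pd.read_csv(path))


def write_exclusions(iv: ExclusionIntervals, path: str | Path) -> None:
    iv.to_frame().to_csv(path, index=False)


def read_roster(calves_path: str | Path, health_path: str | Path | None = None) -> Roster:
    calves = pd.read_csv(calves_path)
    health = (
        pd.read_csv(health_path)
        if health_path is not None and Path(health_path).exists()
        else pd.DataFrame()
    )
    return Roster(calves=calves, health=health)


def write_roster(roster: Roster, out_dir: str | Path) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    calves_path = out / "roster_calves.csv"
    health_path = out / "roster_health.csv"
    roster.calves.to_csv(calves_path, index=False)
    roster.health.to_csv(health_path, index=False)
    return calves_path, health_path


def pen_from_dict(d: dict) -> PenGeometry:
    if isinstance(d, str):
        return (
            PenGeometry.pair_default() if d == "pair" else PenGeometry.group_default()
        )
    return PenGeometry(**d)


def metric_sim_config_from_dict(d: dict) -> MetricSimConfig:
    d = dict(d)
    fe = d.pop("fixed_effects", None)
    if fe is not None:
        d["fixed_effects"] = FixedEffects(**fe)
    return MetricSimConfig(**d)


def trajectory_sim_config_from_dict(d: dict) -> TrajectorySimConfig:
    d = dict(d)
    if "pen" in d:
        d["pen"] = pen_from_dict(d["pen"])
    if "attraction_points" in d and d["attraction_points"] is not None:
        d["attraction_points"] = tuple(tuple(p) for p in d["attraction_points"])
    return TrajectorySimConfig(**d)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
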