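import numpy as np
import pandas as pd
import pytest

from calfmove import simgen


UNIT_FE = simgen.FixedEffects(
    intercept=10.0, day=0.05, age=0.1, housing=2.0,
    health_sick=-1.0, health_convalescent=-0.5,
)


def unit_cfg(**kwargs) -> simgen.MetricSimConfig:
    """Metric-sim config on unit scale; override any field."""
    defaults = dict(
        n_cohorts=6,
        calves_per_cohort=16,
        days_per_housing=20,
        fixed_effects=UNIT_FE,
        var_cohort=0.05,
        var_ind_intercept=0.25,
        var_ind_slope=0.0,
        cor_intercept_slope=0.0,
        var_resid=0.75,
        conformity_weight=0.0,
        seed=0,
    )
    defaults.update(kwargs)
    return simgen.MetricSimConfig(**defaults)


@pytest.fixture(scope="session")
def std_roster() -> "simgen.Roster":
    return simgen.make_roster(6, 16, seed=1)


@pytest.fixture(scope="session")
def small_roster():
    return simgen.make_roster(2, 4, seed=7)


@pytest.fixture(scope="session")
def unit_panel(std_roster):
    """One standard panel with individual intercept variance only."""
    panel, truth = simgen.simulate_metric_panel(std_roster, unit_cfg(seed=11))
    return panel, truth


def toy_two_calf_panel(sep: float = 100.0, n_days: int = 10) -> pd.DataFrame:
    """Balanced 2-calf panel with means 0 and ``sep``."""
    rng = np.random.default_rng(5)
    rows = []
    for calf, mean in (("a", 0.0), ("b", sep)):
        for d in range(n_days):
            rows.append(
                dict(calf_id=calf, date=d, metric_name="distance",
                     value=mean + rng.normal(0, 0.1),
                     day_of_observation=float(d + 1), age=36.6,
                     housing="pair", health="healthy", cohort_id="coh1")
            )
    return pd.DataFrame(rows)
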