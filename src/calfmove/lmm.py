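"""Mixed-model layer: random-intercept and random-slope fits, adjusted
repeatability with parametric-bootstrap CIs, the personality-plasticity
(intercept-slope) correlation, and the pen-mate carry-over model.

All models are Gaussian linear mixed models fitted by REML with a cohort
random intercept and individual random effects nested in cohorts.  Fixed
effects follow the panel contract: day of observation (continuous), age,
housing (pair = 0, group = 1) and health (reference level healthy).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._reml import ConvergenceError, REMLProblem, REMLResult
from .types import HOUSING_LEVELS

__all__ = [
    "LMMFit",
    "RepeatabilityResult",
    "PlasticityCorrelationResult",
    "fit_random_intercept",
    "fit_random_slope",
    "housing_intercepts",
    "adjusted_repeatability",
    "personality_plasticity_correlation",
    "fit_carryover",
    "plot_intercept_slope",
]

_SINGULAR_TOL = 1e-8
MIN_INDIVIDUALS = 20  # accepted standard for repeatability designs


@dataclass
class LMMFit:
    beta: pd.DataFrame  # index: term; columns: estimate, se, t, p
    var_components: dict[str, float]
    individual_effects: pd.DataFrame  # calf_id, intercept_dev [, slope_dev]
    cohort_effects: pd.DataFrame  # cohort_id, effect
    loglik: float
    n_obs: int
    n_individuals: int
    converged: bool
    singular: bool
    metadata: dict = field(default_factory=dict)
    _problem: REMLProblem | None = field(default=None, repr=False)
    _result: REMLResult | None = field(default=None, repr=False)

    @property
    def has_slope(self) -> bool:
        return "slope_dev" in self.individual_effects.columns

    def summary(self) -> str:
        lines = ["Fixed effects:", self.beta.to_string(), "", "Variance components:"]
        lines += [f"  {k} = {v:.6g}" for k, v in self.var_components.items()]
        lines += [
            f"logLik = {self.loglik:.4f}  n_obs = {self.n_obs}  "
            f"n_individuals = {self.n_individuals}",
        ]
        if self.singular:
            lines.append("WARNING: singular fit (a variance component is ~0)")
        return "\n".join(lines)


@dataclass
class RepeatabilityResult:
    R: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int | None

    def __str__(self) -> str:
        return f"R = {self.R:.3f} [{self.ci_low:.3f}, {self.ci_high:.3f}]"


@dataclass
class PlasticityCorrelationResult:
    r: float
    p_value: float
    n: int
    source: str  # predicted_effects | model_parameter


def _prepare(data: pd.DataFrame, include_disease: bool) -> pd.DataFrame:
    d = data.copy()
    if not include_disease:
        d = d[d["health"] == "healthy"]
    return d.reset_index(drop=True)


def _design(
    d: pd.DataFrame,
    include_housing: bool,
    extra: pd.DataFrame | None = None,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(d))]
    names = ["(Intercept)"]
    cols.append(d["day_of_observation"].to_numpy(float))
    names.append("day")
    cols.append(d["age"].to_numpy(float))
    names.append("age")
    if include_housing:
        cols.append((d["housing"] == "group").astype(float).to_numpy())
        names.append("housing[group]")
    for level in ("sick", "convalescent"):
        if (d["health"] == level).any():
            cols.append((d["health"] == level).astype(float).to_numpy())
            names.append(f"health[{level}]")
    if extra is not None:
        for c in extra.columns:
            cols.append(extra[c].to_numpy(float))
            names.append(c)
    return np.column_stack(cols), names


def _codes(d: pd.DataFrame):
    coh = pd.Categorical(d["cohort_id"])
    calf = pd.Categorical(d["calf_id"])
    return (
        np.asarray(coh.codes),
        list(coh.categories),
        np.asarray(calf.codes),
        list(calf.categories),
    )


def _check_min_individuals(d: pd.DataFrame) -> None:
    counts = d.groupby("calf_id").size()
    n_ok = int((counts >= 2).sum())
    if n_ok < MIN_INDIVIDUALS:
        warnings.warn(
            f"only {n_ok} individuals with >= 2 observations; the accepted "
            f"standard for repeatability designs is {MIN_INDIVIDUALS}",
            UserWarning,
            stacklevel=3,
        )


def _finalize(
    problem: REMLProblem,
    result: REMLResult,
    term_names: list[str],
    cohort_labels: list,
    calf_labels: list,
    metadata: dict,
) -> LMMFit:
    vc = problem.variance_components(result)
    coh_u, calf_int, calf_slope = problem.split_ranef(result)
    eff = pd.DataFrame({"calf_id": calf_labels, "intercept_dev": calf_int})
    if calf_slope is not None:
        eff["slope_dev"] = calf_slope
    df_resid = result.n_obs - result.n_fixed
    tvals = result.beta / result.se_beta
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    beta = pd.DataFrame(
        {"estimate": result.beta, "se": result.se_beta, "t": tvals, "p": pvals},
        index=pd.Index(term_names, name="term"),
    )
    singular = any(
        v < _SINGULAR_TOL * vc["V_e0"]
        for k, v in vc.items()
        if k.startswith("V_") and k != "V_e0"
    )
    metadata = dict(metadata)
    metadata.setdefault("p_value_method", "t approximation on residual df")
    metadata.setdefault("reml", problem.reml)
    return LMMFit(
        beta=beta,
        var_components=vc,
        individual_effects=eff,
        cohort_effects=pd.DataFrame({"cohort_id": cohort_labels, "effect": coh_u}),
        loglik=result.loglik,
        n_obs=result.n_obs,
        n_individuals=len(calf_labels),
        converged=result.converged,
        singular=singular,
        metadata=metadata,
        _problem=problem,
        _result=result,
    )


def fit_random_intercept(
    data: pd.DataFrame,
    include_disease: bool = True,
    include_housing: bool = True,
    reml: bool = True,
    extra_fixed: pd.DataFrame | None = None,
) -> LMMFit:
    """Fit the random-intercept model: fixed day/age/housing/health plus
    nested cohort and individual random intercepts."""
    d = _prepare(data, include_disease)
    if include_housing and d["housing"].nunique() < 2:
        include_housing = False
    _check_min_individuals(d)
    X, names = _design(d, include_housing, extra_fixed)
    coh_codes, coh_labels, calf_codes, calf_labels = _codes(d)
    problem = REMLProblem(X, coh_codes, calf_codes, housing=None, reml=reml)
    result = problem.fit(d["value"].to_numpy(float))
    return _finalize(
        problem, result, names, coh_labels, calf_labels,
        {"model": "random_intercept", "include_disease": include_disease},
    )


def fit_random_slope(
    data: pd.DataFrame,
    include_disease: bool = True,
    reml: bool = True,
) -> LMMFit:
    """Fit the random-slope model: as the intercept model, plus a
    per-individual housing slope with unstructured 2x2 covariance."""
    d = _prepare(data, include_disease)
    if d["housing"].nunique() < 2:
        raise ValueError(
            "random-slope model requires observations in both housings; "
            f"found only {sorted(d['housing'].unique())}"
        )
    both = d.groupby("calf_id")["housing"].nunique()
    if int((both == 2).sum()) < MIN_INDIVIDUALS:
        warnings.warn(
            f"only {int((both == 2).sum())} individuals observed in both "
            "housings; slope estimates may be unstable",
            UserWarning,
            stacklevel=2,
        )
    X, names = _design(d, include_housing=True)
    coh_codes, coh_labels, calf_codes, calf_labels = _codes(d)
    housing01 = (d["housing"] == "group").astype(float).to_numpy()
    problem = REMLProblem(X, coh_codes, calf_codes, housing=housing01, reml=reml)
    result = problem.fit(d["value"].to_numpy(float))
    return _finalize(
        problem, result, names, coh_labels, calf_labels,
        {"model": "random_slope", "include_disease": include_disease},
    )


def housing_intercepts(
    data: pd.DataFrame, housing: str, include_disease: bool = True
) -> pd.DataFrame:
    """Per-calf predicted intercept deviations from a single-housing
    random-intercept fit (fixed day/age/health; cohort + individual
    random intercepts).  Input to the pen-mate similarity test."""
    if housing not in HOUSING_LEVELS:
        raise ValueError(f"housing must be one of {HOUSING_LEVELS}")
    d = data[data["housing"] == housing]
    if d.empty:
        raise ValueError(f"no rows in housing {housing!r}")
    fit = fit_random_intercept(d, include_disease=include_disease,
                               include_housing=False)
    return fit.individual_effects[["calf_id", "intercept_dev"]].copy()


def adjusted_repeatability(
    fit: LMMFit,
    n_boot: int = 1000,
    seed: int | None = None,
    include_cohort_in_denominator: bool = False,
) -> RepeatabilityResult:
    """Adjusted repeatability R = V_ind0 / (V_ind0 + V_e0), with a
    percentile parametric-bootstrap confidence interval.

    By default the cohort variance is excluded from the denominator; set
    ``include_cohort_in_denominator`` for the broader convention.
    """
    vc = fit.var_components

    def ratio(v: Mapping[str, float]) -> float:
        denom = v["V_ind0"] + v["V_e0"]
        if include_cohort_in_denominator:
            denom += v["V_coh"]
        if denom == 0:
            raise ZeroDivisionError(
                "repeatability undefined: V_ind0 + V_e0 = 0"
            )
        return v["V_ind0"] / denom

    point = ratio(vc)
    if n_boot <= 0 or fit._problem is None:
        return RepeatabilityResult(point, np.nan, np.nan, 0, seed)
    problem, result = fit._problem, fit._result
    y_orig = np.array(problem.y, copy=True)
    rng = np.random.default_rng(seed)
    draws = np.empty(n_boot)
    for b in range(n_boot):
        y_star = problem.simulate_response(
            result.beta, vc["V_coh"], vc["V_ind0"], vc["V_e0"], rng,
            var_ind1=vc.get("V_ind1", 0.0), cov_ind01=vc.get("cov_ind01", 0.0),
        )
        try:
            res_b = problem.fit(y_star, theta0=result.theta)
        except ConvergenceError:
            res_b = problem.fit(y_star)
        draws[b] = ratio(problem.variance_components(res_b))
    problem.set_y(y_orig)  # leave the problem on its original response
    lo, hi = np.percentile(draws, [2.5, 97.5])
    if not lo <= point <= hi:
        warnings.warn(
            "bootstrap percentile CI does not bracket the point estimate",
            UserWarning,
            stacklevel=2,
        )
    return RepeatabilityResult(point, float(lo), float(hi), n_boot, seed)


def personality_plasticity_correlation(fit: LMMFit) -> list[PlasticityCorrelationResult]:
    """Pearson correlation between predicted individual intercepts and
    slopes, plus the model-parameter correlation implied by the fitted
    covariance.  The predicted-effect correlation is attenuated by
    shrinkage; both views are reported."""
    if not fit.has_slope:
        raise ValueError("fit has no individual slopes; use fit_random_slope")
    eff = fit.individual_effects
    n = len(eff)
    if n < 3:
        raise ValueError(f"need >= 3 individuals, got {n}")
    r, p = stats.pearsonr(eff["intercept_dev"], eff["slope_dev"])
    out = [PlasticityCorrelationResult(float(r), float(p), n, "predicted_effects")]
    vc = fit.var_components
    denom = np.sqrt(vc["V_ind0"] * vc["V_ind1"])
    rho = vc["cov_ind01"] / denom if denom > 0 else np.nan
    out.append(PlasticityCorrelationResult(float(rho), np.nan, n, "model_parameter"))
    return out


def fit_carryover(
    group_data: pd.DataFrame,
    own_pair_intercepts: Mapping,
    penmate_pair_intercepts: Mapping,
    include_disease: bool = True,
) -> LMMFit:
    """Model group-housing observations with the calf's own and its
    pen-mate's pair-housing predicted intercepts as extra fixed effects.
    """
    if (group_data["housing"] != "group").any():
        bad = sorted(group_data.loc[group_data["housing"] != "group", "housing"]
                     .unique())
        raise ValueError(f"group_data must contain group housing only; found {bad}")
    calves = group_data["calf_id"].unique()
    missing = [c for c in calves if c not in penmate_pair_intercepts]
    if missing:
        raise ValueError(f"missing pen-mate intercepts for calves: {missing}")
    missing = [c for c in calves if c not in own_pair_intercepts]
    if missing:
        raise ValueError(f"missing own intercepts for calves: {missing}")
    extra = pd.DataFrame(
        {
            "own_intercept": group_data["calf_id"].map(dict(own_pair_intercepts)),
            "penmate_intercept": group_data["calf_id"].map(
                dict(penmate_pair_intercepts)
            ),
        }
    )
    return fit_random_intercept(
        group_data,
        include_disease=include_disease,
        include_housing=False,
        extra_fixed=extra.reset_index(drop=True),
    )


def plot_intercept_slope(fit: LMMFit, ax=None):
    """Diagnostic scatter of predicted individual intercepts vs slopes."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    eff = fit.individual_effects
    ax.scatter(eff["intercept_dev"], eff["slope_dev"], s=18, alpha=0.8)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("individual intercept deviation (personality)")
    ax.set_ylabel("individual slope deviation (plasticity)")
    return ax
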