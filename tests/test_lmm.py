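import numpy as np
import pandas as pd
import pytest

from calfmove import lmm, simgen
from calfmove.lmm import (
    LMMFit,
    adjusted_repeatability,
    fit_carryover,
    fit_random_intercept,
    fit_random_slope,
    housing_intercepts,
    personality_plasticity_correlation,
)

from conftest import toy_two_calf_panel, unit_cfg


def make_fit(v_ind0, v_e0, v_coh=0.0):
    """Bare LMMFit carrying only variance components (no problem handle)."""
    return LMMFit(
        beta=pd.DataFrame(), var_components={"V_coh": v_coh, "V_ind0": v_ind0,
                                             "V_e0": v_e0},
        individual_effects=pd.DataFrame({"calf_id": [], "intercept_dev": []}),
        cohort_effects=pd.DataFrame(), loglik=0.0, n_obs=0, n_individuals=0,
        converged=True, singular=False,
    )


class TestRandomInterceptFit:
    def test_degenerate_generator_variances(self, std_roster):
        cfg = unit_cfg(var_cohort=0.0, var_ind_intercept=0.0, seed=22)
        panel, _ = simgen.simulate_metric_panel(std_roster, cfg)
        fit = fit_random_intercept(panel)
        assert fit.var_components["V_ind0"] < 1e-6 * fit.var_components["V_e0"]
        assert fit.singular
        fe = cfg.fixed_effects
        truth = {"(Intercept)": fe.intercept, "day": fe.day, "age": fe.age,
                 "housing[group]": fe.housing, "health[sick]": fe.health_sick,
                 "health[convalescent]": fe.health_convalescent}
        for term, true_val in truth.items():
            est = fit.beta.loc[term]
            assert abs(est["estimate"] - true_val) < 3 * est["se"]

    def test_matches_statsmodels(self, unit_panel):
        """Independent-route check of the REML engine on the nested
        intercept structure."""
        import statsmodels.formula.api as smf

        panel, _ = unit_panel
        fit = fit_random_intercept(panel)
        d = panel.copy()
        d["housing01"] = (d["housing"] == "group").astype(float)
        d["sick"] = (d["health"] == "sick").astype(float)
        d["conv"] = (d["health"] == "convalescent").astype(float)
        sm_fit = smf.mixedlm(
            "value ~ day_of_observation + age + housing01 + sick + conv",
            d, groups=d["cohort_id"], re_formula="1",
            vc_formula={"calf": "0 + C(calf_id)"},
        ).fit(reml=True)
        assert fit.var_components["V_e0"] == pytest.approx(sm_fit.scale, rel=1e-3)
        assert fit.var_components["V_ind0"] == pytest.approx(
            float(sm_fit.vcomp[0]), rel=1e-3)
        assert fit.var_components["V_coh"] == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-2)
        np.testing.assert_allclose(
            fit.beta["estimate"].to_numpy()[1:],  # skip intercept ordering
            sm_fit.fe_params.to_numpy()[1:], rtol=1e-4)

    def test_variance_recovery(self, std_roster):
        ests = []
        for seed in range(20):
            panel, _ = simgen.simulate_metric_panel(
                std_roster, unit_cfg(seed=300 + seed))
            ests.append(fit_random_intercept(panel).var_components["V_ind0"])
        assert np.mean(ests) == pytest.approx(0.25, abs=0.04)

    def test_two_individual_ordering(self):
        panel = toy_two_calf_panel(sep=100.0)
        with pytest.warns(UserWarning, match="individuals"):
            fit = fit_random_intercept(panel)
        eff = fit.individual_effects.set_index("calf_id")["intercept_dev"]
        assert eff["b"] > eff["a"]

    def test_refit_is_deterministic(self, unit_panel):
        panel, _ = unit_panel
        f1 = fit_random_intercept(panel)
        f2 = fit_random_intercept(panel)
        assert f1.var_components == f2.var_components
        pd.testing.assert_frame_equal(f1.beta, f2.beta)

    def test_individual_deviations_centred(self, unit_panel):
        panel, _ = unit_panel
        fit = fit_random_intercept(panel)
        dev = fit.individual_effects["intercept_dev"]
        assert abs(dev.mean()) < 1e-6 * dev.std()

    def test_metadata_declares_p_method(self, unit_panel):
        panel, _ = unit_panel
        fit = fit_random_intercept(panel)
        assert "p_value_method" in fit.metadata
        assert fit.metadata["reml"] is True

    def test_exclude_disease_drops_rows(self, std_roster):
        panel, _ = simgen.simulate_metric_panel(std_roster, unit_cfg(seed=31))
        if not (panel["health"] != "healthy").any():
            pytest.skip("no disease episodes drawn")
        fit_incl = fit_random_intercept(panel, include_disease=True)
        fit_excl = fit_random_intercept(panel, include_disease=False)
        assert fit_excl.n_obs < fit_incl.n_obs
        assert not any(t.startswith("health[") for t in fit_excl.beta.index)


class TestAdjustedRepeatability:
    def test_eq_arithmetic(self):
        assert adjusted_repeatability(make_fit(1.0, 3.0), n_boot=0).R == 0.25

    def test_zero_individual_variance(self):
        assert adjusted_repeatability(make_fit(0.0, 2.0), n_boot=0).R == 0.0

    def test_undefined_ratio_raises(self):
        with pytest.raises(ZeroDivisionError):
            adjusted_repeatability(make_fit(0.0, 0.0), n_boot=0)

    def test_cohort_denominator_option(self):
        fit = make_fit(1.0, 2.0, v_coh=1.0)
        assert adjusted_repeatability(fit, n_boot=0).R == pytest.approx(1 / 3)
        assert adjusted_repeatability(
            fit, n_boot=0, include_cohort_in_denominator=True
        ).R == pytest.approx(0.25)

    def test_bootstrap_ci_brackets_point(self, unit_panel):
        panel, _ = unit_panel
        fit = fit_random_intercept(panel)
        rep = adjusted_repeatability(fit, n_boot=60, seed=5)
        assert rep.ci_low <= rep.R <= rep.ci_high
        assert 0.0 <= rep.ci_low and rep.ci_high <= 1.0

    def test_bootstrap_deterministic(self, unit_panel):
        panel, _ = unit_panel
        fit = fit_random_intercept(panel)
        r1 = adjusted_repeatability(fit, n_boot=20, seed=9)
        r2 = adjusted_repeatability(fit, n_boot=20, seed=9)
        assert (r1.R, r1.ci_low, r1.ci_high) == (r2.R, r2.ci_low, r2.ci_high)


class TestRandomSlopeFit:
    def test_zero_slope_variance_recovered(self, std_roster):
        # a boundary REML fit: with true slope variance 0 the estimate sits
        # at (or within sampling noise of) zero; this seed lands on zero
        panel, _ = simgen.simulate_metric_panel(
            std_roster, unit_cfg(var_ind_slope=0.0, seed=46))
        fit = fit_random_slope(panel)
        assert fit.var_components["V_ind1"] < 1e-4 * fit.var_components["V_e0"]

    def test_single_housing_rejected(self, unit_panel):
        panel, _ = unit_panel
        with pytest.raises(ValueError, match="both housings"):
            fit_random_slope(panel[panel["housing"] == "pair"])

    def test_covariance_inequality(self, std_roster):
        panel, _ = simgen.simulate_metric_panel(
            std_roster,
            unit_cfg(var_ind_slope=0.25, cor_intercept_slope=0.6, seed=42))
        vc = fit_random_slope(panel).var_components
        assert abs(vc["cov_ind01"]) <= np.sqrt(vc["V_ind0"] * vc["V_ind1"]) + 1e-12

    def test_positive_correlation_recovered(self, std_roster):
        panel, _ = simgen.simulate_metric_panel(
            std_roster,
            unit_cfg(var_ind_slope=0.25, cor_intercept_slope=0.6, seed=43))
        fit = fit_random_slope(panel)
        cors = personality_plasticity_correlation(fit)
        by_source = {c.source: c for c in cors}
        assert by_source["predicted_effects"].r > 0
        assert by_source["model_parameter"].r > 0


class TestPlasticityCorrelation:
    def test_affine_slopes_give_unit_correlation(self):
        eff = pd.DataFrame(
            {"calf_id": list("abcdef"),
             "intercept_dev": [1.0, 2, 3, 4, 5, 6]}
        )
        eff["slope_dev"] = 2.0 * eff["intercept_dev"] - 1.0
        fit = make_fit(1.0, 1.0)
        fit.individual_effects = eff
        fit.var_components.update({"V_ind1": 4.0, "cov_ind01": 2.0})
        cors = personality_plasticity_correlation(fit)
        assert cors[0].r == pytest.approx(1.0)
        eff["slope_dev"] = -eff["slope_dev"]
        fit.var_components["cov_ind01"] = -2.0
        assert personality_plasticity_correlation(fit)[0].r == pytest.approx(-1.0)

    def test_needs_slope(self, unit_panel):
        panel, _ = unit_panel
        fit = fit_random_intercept(panel)
        with pytest.raises(ValueError, match="slope"):
            personality_plasticity_correlation(fit)

    def test_needs_three_individuals(self):
        fit = make_fit(1.0, 1.0)
        fit.individual_effects = pd.DataFrame(
            {"calf_id": ["a", "b"], "intercept_dev": [0.0, 1.0],
             "slope_dev": [0.0, 1.0]}
        )
        with pytest.raises(ValueError, match=">= 3"):
            personality_plasticity_correlation(fit)


class TestHousingIntercepts:
    def test_returns_all_calves(self, unit_panel):
        panel, _ = unit_panel
        eff = housing_intercepts(panel, "pair")
        assert len(eff) == panel["calf_id"].nunique()
        assert set(eff.columns) == {"calf_id", "intercept_dev"}

    def test_unknown_housing(self, unit_panel):
        panel, _ = unit_panel
        with pytest.raises(ValueError):
            housing_intercepts(panel, "solitary")

    def test_tracks_true_intercepts(self, std_roster):
        cfg = unit_cfg(var_ind_intercept=1.0, var_resid=0.25, seed=51)
        panel, truth = simgen.simulate_metric_panel(std_roster, cfg)
        eff = housing_intercepts(panel, "pair").set_index("calf_id")
        merged = truth.calf_effects.set_index("calf_id").join(eff)
        r = np.corrcoef(merged["b0_pair_effective"], merged["intercept_dev"])[0, 1]
        assert r > 0.9


class TestCarryover:
    @staticmethod
    def _panel_with_carryover(roster, gamma, seed):
        cfg = unit_cfg(seed=seed)
        panel, truth = simgen.simulate_metric_panel(roster, cfg)
        b0 = truth.calf_effects.set_index("calf_id")["b0"]
        mates = roster.pair_of()
        mate_b0 = panel["calf_id"].map(lambda c: b0[mates[c]])
        panel = panel.copy()
        panel.loc[panel["housing"] == "group", "value"] += (
            gamma * mate_b0[panel["housing"] == "group"]
        )
        own = dict(b0)
        mate = {c: b0[mates[c]] for c in b0.index}
        return panel, own, mate

    def test_pair_rows_rejected(self, std_roster):
        panel, own, mate = self._panel_with_carryover(std_roster, 0.0, 61)
        with pytest.raises(ValueError, match="group housing only"):
            fit_carryover(panel, own, mate)

    def test_missing_penmate_listed(self, std_roster):
        panel, own, mate = self._panel_with_carryover(std_roster, 0.0, 62)
        group = panel[panel["housing"] == "group"]
        victim = group["calf_id"].iloc[0]
        mate.pop(victim)
        with pytest.raises(ValueError, match=str(victim)):
            fit_carryover(group, own, mate)

    def test_negative_effect_recovered(self, std_roster):
        panel, own, mate = self._panel_with_carryover(std_roster, -0.79, 63)
        group = panel[panel["housing"] == "group"]
        fit = fit_carryover(group, own, mate)
        est = fit.beta.loc["penmate_intercept"]
        assert est["estimate"] < 0
        assert abs(est["estimate"] - (-0.79)) < 3 * est["se"]

    def test_null_effect_near_zero(self, std_roster):
        panel, own, mate = self._panel_with_carryover(std_roster, 0.0, 64)
        group = panel[panel["housing"] == "group"]
        fit = fit_carryover(group, own, mate)
        est = fit.beta.loc["penmate_intercept"]
        assert abs(est["estimate"]) < 3 * est["se"]
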