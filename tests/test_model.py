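"""Mortality model: coverage effect, expected rates, anchoring, prediction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import esfsim as es
from esfsim.model import BASE_YEAR

from conftest import flat_effects, single_muni_panel

ZERO_COVS = {c: 0.0 for c in es.COVARIATES}


class TestCoverageEffect:
    def test_full_coverage_past_lag_reaches_full_effect(self, effects):
        eff = es.coverage_effect(1.0, 10, effects, "nutritional")
        assert eff == pytest.approx(np.log(0.48))

    def test_zero_coverage_is_neutral(self, effects):
        assert es.coverage_effect(0.0, 10, effects, "nutritional") == 0.0

    def test_half_coverage_halves_the_log_effect(self, effects):
        eff = es.coverage_effect(0.5, 10, effects, "nutritional")
        assert np.exp(eff) == pytest.approx(0.48**0.5)

    def test_duration_ramp_phases_effect_in(self, effects):
        lag = effects.duration_lag_years
        partial = es.coverage_effect(1.0, lag / 2, effects, "nutritional")
        assert partial == pytest.approx(0.5 * np.log(0.48))

    def test_categorical_classes(self, effects):
        lnrr = np.log(0.48)
        full = es.coverage_effect(0.9, 10, effects, "nutritional", "categorical")
        young = es.coverage_effect(0.9, 1, effects, "nutritional", "categorical")
        low = es.coverage_effect(0.5, 10, effects, "nutritional", "categorical")
        assert full == pytest.approx(lnrr)
        assert young == pytest.approx(0.5 * lnrr)
        assert low == 0.0

    def test_unknown_parameterization_rejected(self, effects):
        with pytest.raises(ValueError, match="parameterization"):
            es.coverage_effect(0.5, 5, effects, "nutritional", "quadratic")

    def test_duration_counter_resets_on_interruption(self):
        cov = np.array([[0.5, 0.5, 0.0, 0.5, 0.5]])
        dur = es.coverage_duration(cov)
        np.testing.assert_array_equal(dur[0], [1, 2, 0, 1, 2])


class TestExpectedRate:
    def test_intercept_only(self):
        table = flat_effects(gamma=0.0)
        rate = es.expected_rate(
            ZERO_COVS, 0.0, 0, np.log(50.0), table, "acsc_total", 2015
        )
        assert rate == pytest.approx(50.0)

    def test_full_coverage_applies_rate_ratio(self):
        table = flat_effects(rr_full=0.48, gamma=0.0)
        rate = es.expected_rate(
            ZERO_COVS, 1.0, 10, np.log(50.0), table, "acsc_total", 2015
        )
        assert rate == pytest.approx(24.0)

    def test_secular_trend_closed_form(self):
        table = flat_effects(gamma=-0.02)
        rate = es.expected_rate(
            ZERO_COVS, 0.0, 0, np.log(50.0), table, "acsc_total", 2020
        )
        assert rate == pytest.approx(50.0 * np.exp(-0.2))

    def test_missing_covariate_named_in_error(self, effects):
        covs = dict(ZERO_COVS)
        covs.pop("urbanisation")
        with pytest.raises(KeyError, match="urbanisation"):
            es.expected_rate(covs, 0.0, 0, 0.0, effects, "acsc_total", 2015)

    @given(
        c1=st.floats(0.0, 1.0),
        c2=st.floats(0.0, 1.0),
        duration=st.floats(0.0, 20.0),
        alpha=st.floats(1.0, 6.0),
    )
    @settings(max_examples=120, deadline=None)
    def test_monotone_nonincreasing_in_coverage(self, c1, c2, duration, alpha):
        table = flat_effects(rr_full=0.7)
        lo_cov, hi_cov = sorted((c1, c2))
        r_lo = es.expected_rate(
            ZERO_COVS, hi_cov, duration, alpha, table, "acsc_total", 2015
        )
        r_hi = es.expected_rate(
            ZERO_COVS, lo_cov, duration, alpha, table, "acsc_total", 2015
        )
        assert r_lo <= r_hi + 1e-12


class TestFixedEffectAnchoring:
    def test_exact_recovery_from_noise_free_deaths(self, small_params):
        base = es.assign_mmp_doctors(
            es.generate_cohort(small_params), small_params
        )
        panel = es.generate_deaths(base, distribution="expected")
        truth = panel.truth["alphas"]
        for stratum in ("acsc_total", "nutritional", "acsc_black"):
            rec = es.estimate_fixed_effects(
                panel, small_params.true_effects, stratum
            )
            err = np.abs(rec - truth[stratum].reindex(rec.index)).max()
            assert err < 1e-8

    def test_all_zero_deaths_sit_at_continuity_floor_and_flagged(self):
        panel = single_muni_panel(rate=0.0, n_munis=3)
        table = flat_effects()
        alphas = es.estimate_fixed_effects(panel, table, "acsc_total")
        # floor: log(0.5 / person-years * 1e5) with zero model offsets
        expected_floor = np.log(0.5 / 100_000 * 1e5)
        assert np.allclose(alphas, expected_floor)
        assert len(alphas.attrs["degenerate"]) == 3

    def test_anchoring_unbiased_at_high_counts(self):
        # 200 replicate municipalities with ~200 expected deaths per year:
        # the mean log-rate anchoring is unbiased to first order (the
        # E[ln X] Poisson bias ~ -1/(2 mu) is negligible here)
        rate, pop, n = 100.0, 200_000.0, 200
        panel = single_muni_panel(rate=rate, population=pop, n_munis=n)
        table = flat_effects()
        true_alpha = np.log(rate)
        alphas_in = {"acsc_total": pd.Series(true_alpha, index=panel.muni_ids)}
        drawn = es.generate_deaths(
            panel, table, seed=21, alphas=alphas_in,
            params=es.CohortParams(n_municipalities=2),
        )
        rec = es.estimate_fixed_effects(drawn, table, "acsc_total")
        errors = rec.to_numpy() - true_alpha
        se = errors.std(ddof=1) / np.sqrt(n)
        assert abs(errors.mean()) < 3 * se


class TestPredictPanel:
    def test_prediction_set_cardinality(self, small_cohort, effects):
        ext = es.forecast_panel(small_cohort, 2030)
        trajs = {
            name: es.apply_scenario(ext, spec)
            for name, spec in es.default_scenarios().items()
        }
        fe = {
            s: es.estimate_fixed_effects(small_cohort, effects, s)
            for s in ("acsc_total", "infectious")
        }
        preds = es.predict_panel(
            ext, trajs, fe, effects, ["acsc_total", "infectious"]
        )
        n, years = small_cohort.n_municipalities, 21
        assert len(preds) == n * years * 4 * 2
        assert (preds["rate"] > 0).all()

    def test_identical_trajectories_give_identical_predictions(
        self, small_cohort, effects
    ):
        ext = es.forecast_panel(small_cohort, 2030)
        traj = es.apply_scenario(ext, es.ScenarioSpec("status_quo"))
        fe = {"acsc_total": es.estimate_fixed_effects(small_cohort, effects, "acsc_total")}
        preds = es.predict_panel(
            ext, {"a": traj, "b": traj.copy()}, fe, effects, ["acsc_total"]
        )
        a = preds.query("scenario == 'a'")["rate"].to_numpy()
        b = preds.query("scenario == 'b'")["rate"].to_numpy()
        np.testing.assert_array_equal(a, b)

    def test_frozen_model_declines_at_the_secular_rate(self):
        # constant covariates and coverage: consecutive-year rate ratio e^gamma
        table = flat_effects(rr_full=0.8, gamma=-0.022)
        panel = single_muni_panel(coverage=0.6, years=range(2010, 2031))
        fe = {"acsc_total": pd.Series(np.log(50.0), index=panel.muni_ids)}
        preds = es.predict_panel(panel, {"s": None}, fe, table, ["acsc_total"])
        by_year = preds.set_index("year")["rate"].sort_index()
        ratios = (by_year.values[5:] / by_year.values[4:-1])  # past the ramp
        np.testing.assert_allclose(ratios, np.exp(-0.022), rtol=1e-10)

    def test_higher_coverage_trajectory_lowers_rates_everywhere(
        self, small_cohort, effects
    ):
        ext = es.forecast_panel(small_cohort, 2030)
        specs = es.default_scenarios()
        fe = {"acsc_total": es.estimate_fixed_effects(small_cohort, effects, "acsc_total")}
        preds = es.predict_panel(
            ext,
            {k: es.apply_scenario(ext, v) for k, v in specs.items()},
            fe,
            effects,
            ["acsc_total"],
        )
        wide = preds.pivot_table(
            index=["muni_id", "year"], columns="scenario", values="rate"
        )
        future = wide[wide.index.get_level_values("year") >= 2017]
        assert (future["uhc"] <= future["status_quo"] + 1e-12).all()
        assert (future["status_quo"] <= future["austerity"] + 1e-12).all()
        assert (future["austerity"] <= future["austerity_mmp_end"] + 1e-12).all()


class TestModelResultsAPI:
    def test_fit_predict_and_summary(self, small_cohort, effects):
        model = es.ACSCMortalityModel(small_cohort, effects, stratum="acsc_total")
        res = model.fit()
        assert res.fixed_effects.index.is_unique
        preds = res.predict(years=(2010, 2016))
        assert set(preds.columns) == {"muni_id", "year", "rate"}
        text = res.summary()
        assert "acsc_total" in text and "full ESF coverage" in text

    def test_params_expose_log_rate_ratios(self, small_cohort, effects):
        res = es.ACSCMortalityModel(small_cohort, effects, stratum="infectious").fit()
        assert res.params["ln_rr_full_coverage"] == pytest.approx(np.log(0.79))
        assert res.params["gamma"] == pytest.approx(effects["infectious"].gamma)

    def test_fit_with_observed_series_recalibrates_gamma(self, small_cohort, effects):
        # a series declining faster than the default trend must lower gamma
        years = range(2010, 2016)
        obs = {y: 100.0 * np.exp(-0.06 * (y - 2010)) for y in years}
        model = es.ACSCMortalityModel(small_cohort, effects, stratum="acsc_total")
        res = model.fit(observed=obs)
        assert res.effects["acsc_total"].gamma < effects["acsc_total"].gamma
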