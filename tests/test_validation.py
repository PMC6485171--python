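"""Calibration, internal/external validation, sensitivity harness."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import esfsim as es
from esfsim.validation import (
    ObservedSeries,
    _national_mean_rates,
    internal_validation,
    simulate_outcome_panel,
)

YEARS = list(range(2010, 2016))


def _with_gamma(effects, stratum, gamma):
    return dataclasses.replace(
        effects,
        strata={
            **effects.strata,
            stratum: dataclasses.replace(effects.strata[stratum], gamma=gamma),
        },
    )


@pytest.fixture(scope="module")
def calib_inputs(bundle):
    ext = bundle.extended_panel
    current = _national_mean_rates(
        ext, bundle.effects, "acsc_total", YEARS, (2010, 2016), "continuous"
    )
    return ext, bundle.effects, current


class TestSecularTrendCalibration:
    def test_recovers_a_shifted_trend_exactly(self, calib_inputs):
        ext, effects, _ = calib_inputs
        true_gamma = effects["acsc_total"].gamma + 0.015
        shifted = _with_gamma(effects, "acsc_total", true_gamma)
        obs = _national_mean_rates(
            ext, shifted, "acsc_total", YEARS, (2010, 2016), "continuous"
        )
        fitted = es.calibrate_secular_trend(
            ext, effects, "acsc_total", ObservedSeries(dict(zip(YEARS, obs)))
        )
        assert fitted == pytest.approx(true_gamma, abs=1e-6)

    def test_fixed_point_when_observed_equals_model_output(self, calib_inputs):
        ext, effects, current = calib_inputs
        fitted = es.calibrate_secular_trend(
            ext, effects, "acsc_total", ObservedSeries(dict(zip(YEARS, current)))
        )
        assert fitted == pytest.approx(effects["acsc_total"].gamma, abs=1e-12)

    def test_two_percent_annual_decline_closed_form(self, calib_inputs):
        ext, effects, current = calib_inputs
        obs = current * 0.98 ** (np.array(YEARS) - 2010)
        fitted = es.calibrate_secular_trend(
            ext, effects, "acsc_total", ObservedSeries(dict(zip(YEARS, obs)))
        )
        assert fitted == pytest.approx(
            effects["acsc_total"].gamma + np.log(0.98), abs=1e-9
        )

    def test_idempotent_after_reanchoring(self, calib_inputs):
        ext, effects, current = calib_inputs
        obs = ObservedSeries(
            dict(zip(YEARS, current * 0.985 ** (np.array(YEARS) - 2010)))
        )
        g1 = es.calibrate_secular_trend(ext, effects, "acsc_total", obs)
        g2 = es.calibrate_secular_trend(
            ext, _with_gamma(effects, "acsc_total", g1), "acsc_total", obs
        )
        assert abs(g2 - g1) < 1e-10

    def test_undernotification_scales_the_target(self, calib_inputs):
        ext, effects, current = calib_inputs
        plain = ObservedSeries(dict(zip(YEARS, current)))
        scaled = ObservedSeries(dict(zip(YEARS, current)), undernotification=1.2)
        g_plain = es.calibrate_secular_trend(ext, effects, "acsc_total", plain)
        g_scaled = es.calibrate_secular_trend(ext, effects, "acsc_total", scaled)
        # a constant multiplicative correction changes the level, not the slope
        assert g_scaled == pytest.approx(g_plain, abs=1e-12)

    def test_nonpositive_observed_rates_rejected(self, calib_inputs):
        ext, effects, _ = calib_inputs
        with pytest.raises(ValueError, match="non-negative"):
            ObservedSeries({2010: -1.0})
        with pytest.raises(ValueError, match="at least two"):
            es.calibrate_secular_trend(
                ext, effects, "acsc_total", ObservedSeries({2010: 50.0})
            )


class TestInternalValidation:
    def test_noise_free_panel_recovers_all_coefficients(self, bundle):
        alphas = bundle.panel.truth["alphas"]["acsc_total"]
        sim = simulate_outcome_panel(
            bundle.extended_panel,
            bundle.trajectories["austerity"],
            bundle.effects,
            alphas,
            "acsc_total",
        )
        report = internal_validation(sim, bundle.effects, "acsc_total")
        assert report.max_coef_deviation < 1e-6
        assert not report.flags

    def test_poisson_noise_keeps_truth_inside_wald_intervals(self, bundle):
        alphas = bundle.panel.truth["alphas"]["acsc_total"]
        sim = simulate_outcome_panel(
            bundle.extended_panel,
            bundle.trajectories["austerity"],
            bundle.effects,
            alphas,
            "acsc_total",
            rng=np.random.default_rng(17),
        )
        report = internal_validation(sim, bundle.effects, "acsc_total")
        # with 10 coefficients at 95% nominal coverage, at most a couple
        # should fall outside in any one replicate
        assert report.coef_table["inside_ci"].mean() >= 0.8

    def test_null_covariate_effect_is_recovered_as_null(self, bundle):
        # set the private-beds effect to exactly zero in the generator and
        # check the fit sees it as null
        table = bundle.effects
        se = table["acsc_total"]
        cov = dict(se.covariates)
        cov["private_beds"] = es.RateRatio(1.0)
        null_table = dataclasses.replace(
            table,
            strata={
                **table.strata,
                "acsc_total": dataclasses.replace(se, covariates=cov),
            },
        )
        alphas = bundle.panel.truth["alphas"]["acsc_total"]
        sim = simulate_outcome_panel(
            bundle.extended_panel,
            bundle.trajectories["austerity"],
            null_table,
            alphas,
            "acsc_total",
            rng=np.random.default_rng(23),
        )
        report = internal_validation(sim, null_table, "acsc_total")
        row = report.coef_table.loc["private_beds"]
        assert abs(row["fitted"]) < 3 * row["se"]


class TestExternalValidation:
    def test_identity_series(self):
        pred = pd.DataFrame(
            {
                "year": YEARS,
                "rate": [100, 95, 91, 87, 83, 80],
                "ci_lo": [90, 85, 81, 77, 73, 70],
                "ci_hi": [110, 105, 101, 97, 93, 90],
            }
        )
        obs = ObservedSeries(dict(zip(YEARS, pred["rate"])))
        report = es.external_validation(pred, obs)
        assert report.slope == pytest.approx(1.0)
        assert report.intercept == pytest.approx(0.0, abs=1e-9)
        assert report.r_squared == pytest.approx(1.0)
        assert report.frac_within_ci == 1.0

    def test_doubled_series_has_slope_two(self):
        pred = pd.DataFrame({"year": YEARS, "rate": [100, 95, 91, 87, 83, 80]})
        obs = ObservedSeries({y: 2.0 * r for y, r in zip(YEARS, [100, 95, 91, 87, 83, 80])})
        report = es.external_validation(pred, obs)
        assert report.slope == pytest.approx(2.0)
        assert report.r_squared == pytest.approx(1.0)

    def test_too_few_overlapping_years_flagged(self):
        pred = pd.DataFrame({"year": [2010, 2011], "rate": [100, 95]})
        report = es.external_validation(pred, ObservedSeries({2010: 99, 2011: 96}))
        assert np.isnan(report.r_squared)
        assert any("overlap" in f for f in report.flags)

    def test_simulated_band_contains_observed_noise(self, bundle):
        # observed = model output + Poisson-scale noise should mostly sit
        # inside the simulated credible band
        summ = es.summarize(bundle.result)
        nat = summ.query(
            "scenario == 'status_quo' and stratum == 'acsc_total' and year <= 2015"
        )
        pred = nat[["year", "mean", "ci_lo", "ci_hi"]].rename(columns={"mean": "rate"})
        rng = np.random.default_rng(5)
        obs = {
            int(y): max(r + rng.normal(scale=0.3), 1.0)
            for y, r in zip(pred["year"], pred["rate"])
        }
        report = es.external_validation(pred, ObservedSeries(obs))
        assert report.frac_within_ci >= 0.9


class TestSensitivityHarness:
    def test_grid_needs_at_least_two_variants(self):
        with pytest.raises(ValueError, match="at least 2"):
            es.SensitivityGrid("decline_magnitude", {"only": 1.0})

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="unknown sensitivity axis"):
            es.SensitivityGrid("tax_policy", {"a": 1, "b": 2})

    def test_decline_magnitude_dose_response(self, deterministic_config):
        cfg = deterministic_config(n_municipalities=80)
        cfg.strata = ["acsc_total"]
        grid = es.SensitivityGrid(
            "decline_magnitude", {"half": 0.5, "base": 1.0, "deeper": 1.5}
        )
        table = es.run_sensitivity(cfg, grid)
        assert (table["error"] == "").all()
        ratios = table.set_index("variant")["ratio_2030_austerity"]
        assert ratios["half"] < ratios["base"] < ratios["deeper"]

    def test_secular_trend_variants_leave_scenario_ratios_unchanged(
        self, deterministic_config
    ):
        cfg = deterministic_config(n_municipalities=80)
        cfg.strata = ["acsc_total"]
        grid = es.SensitivityGrid(
            "secular_trend", {"flatter": 0.011, "base": 0.0, "steeper": -0.011}
        )
        table = es.run_sensitivity(cfg, grid)
        assert (table["error"] == "").all()
        ratios = table["ratio_2030_austerity"].to_numpy()
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-9)
        # absolute excess deaths do shift with the trend
        deaths = table["excess_deaths_austerity"].to_numpy()
        assert deaths.std() > 0

    def test_failed_variant_is_reported_not_dropped(self, deterministic_config):
        cfg = deterministic_config(n_municipalities=80)
        grid = es.SensitivityGrid(
            "poverty_stratified_effect",
            {"bad": [1.0, 1.0, 1.0], "ok": [1.0, 1.0, 1.0, 1.0, 1.0]},
        )
        table = es.run_sensitivity(cfg, grid)
        bad = table.set_index("variant").loc["bad"]
        assert bad["error"] != ""
        assert (table.set_index("variant").loc["ok", "error"]) == ""
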