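"""Monte Carlo engine: effect sampling, determinism, summaries, comparisons."""

import numpy as np
import pandas as pd
import pytest

import esfsim as es
from esfsim.simulate import DrawSpec

from conftest import flat_effects, single_muni_panel


class TestDrawEffects:
    def test_log_scale_sigma_matches_closed_form(self):
        rr = es.RateRatio(0.49, 0.40, 0.60)
        assert rr.sigma == pytest.approx(
            (np.log(0.60) - np.log(0.40)) / (2 * 1.959963984540054)
        )
        assert rr.sigma == pytest.approx(0.10345, abs=2e-4)

    def test_degenerate_interval_draws_are_constant(self, effects):
        table = flat_effects(rr_full=0.48)  # no CIs anywhere
        rng = np.random.default_rng(0)
        sampled = es.draw_effects(table, rng)
        assert sampled["acsc_total"].rr_full.point == 0.48

    def test_quantiles_of_sampled_rr_recover_the_interval(self):
        table = flat_effects(rr_full=0.49, lo=0.40, hi=0.60)
        rng = np.random.default_rng(1)
        draws = np.array(
            [es.draw_effects(table, rng)["acsc_total"].rr_full.point
             for _ in range(10_000)]
        )
        lo, hi = np.quantile(draws, [0.025, 0.975])
        assert lo == pytest.approx(0.40, rel=0.02)
        assert hi == pytest.approx(0.60, rel=0.02)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            es.RateRatio(0.5, 0.6, 0.4)


@pytest.fixture(scope="module")
def sim_inputs(small_cohort, effects):
    ext = es.forecast_panel(small_cohort, 2030)
    trajs = {
        name: es.apply_scenario(ext, spec)
        for name, spec in es.default_scenarios().items()
    }
    return ext, trajs


class TestRunSimulation:
    def test_same_seed_reproduces_the_result(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        spec = DrawSpec(n_draws=20, master_seed=3)
        a = es.run_simulation(ext, trajs, effects, spec)
        b = es.run_simulation(ext, trajs, effects, spec)
        np.testing.assert_array_equal(a.mean_rates, b.mean_rates)
        np.testing.assert_array_equal(a.deaths_total, b.deaths_total)

    def test_sampling_disabled_reduces_to_deterministic_model(
        self, sim_inputs, effects
    ):
        ext, trajs = sim_inputs
        spec = DrawSpec(
            n_draws=1, sample_effects=False, sample_baseline=False, keep_rates=True
        )
        result = es.run_simulation(ext, trajs, effects, spec, strata=["acsc_total"])
        fe = {"acsc_total": es.estimate_fixed_effects(ext, effects, "acsc_total")}
        preds = es.predict_panel(ext, trajs, fe, effects, ["acsc_total"])
        for si, scen in enumerate(result.scenarios):
            wide = (
                preds.query("scenario == @scen")
                .pivot(index="muni_id", columns="year", values="rate")
                .reindex(index=result.muni_ids, columns=list(result.years))
                .values
            )
            np.testing.assert_allclose(
                result.rates[0, si, :, :, 0].T, wide, rtol=1e-12
            )

    def test_shape_contract(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        spec = DrawSpec(n_draws=7)
        result = es.run_simulation(
            ext, trajs, effects, spec, strata=("acsc_total", "infectious")
        )
        assert result.mean_rates.shape == (7, 4, 21, 2)
        assert result.quintile_mean_rates.shape == (7, 4, 21, 2, 5)
        assert (result.mean_rates > 0).all()


class TestSummaries:
    def test_degenerate_draws_have_zero_ci_width(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        spec = DrawSpec(n_draws=5, sample_effects=False, sample_baseline=False)
        result = es.run_simulation(ext, trajs, effects, spec, strata=["acsc_total"])
        summ = es.summarize(result)
        np.testing.assert_allclose(summ["ci_lo"], summ["ci_hi"], rtol=1e-12)
        np.testing.assert_allclose(summ["ci_lo"], summ["mean"], rtol=1e-12)

    def test_quantile_ordering(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        result = es.run_simulation(
            ext, trajs, effects, DrawSpec(n_draws=50, master_seed=2),
            strata=["acsc_total"],
        )
        summ = es.summarize(result)
        assert (summ["ci_lo"] <= summ["ci_hi"]).all()


class TestScenarioRatio:
    def test_self_ratio_is_unit_with_zero_width(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        result = es.run_simulation(
            ext, trajs, effects, DrawSpec(n_draws=30, master_seed=4),
            strata=["acsc_total"],
        )
        rr = es.scenario_ratio(result, "austerity", "austerity", 2030)
        assert rr["ratio"] == pytest.approx(1.0)
        assert rr["ci_lo"] == pytest.approx(1.0) and rr["ci_hi"] == pytest.approx(1.0)

    def test_reciprocity_per_draw(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        result = es.run_simulation(
            ext, trajs, effects, DrawSpec(n_draws=30, master_seed=4),
            strata=["acsc_total"],
        )
        ab = result.mean_rate_draws("austerity", 2030, "acsc_total") / \
            result.mean_rate_draws("status_quo", 2030, "acsc_total")
        ba = result.mean_rate_draws("status_quo", 2030, "acsc_total") / \
            result.mean_rate_draws("austerity", 2030, "acsc_total")
        np.testing.assert_allclose(ab * ba, 1.0, rtol=1e-12)

    def test_single_municipality_deterministic_ratio(self):
        # zero vs full consolidated coverage, nutritional stratum: the
        # deterministic rate ratio must equal 1/0.48
        table = flat_effects(rr_full=0.48, gamma=0.0, stratum="nutritional")
        panel = single_muni_panel(
            rate=30.0, years=range(2010, 2031), coverage=0.0, stratum="nutritional"
        )
        years = pd.DataFrame(
            {"muni_id": "T0000", "year": range(2017, 2031)}
        )
        traj_zero = years.assign(esf_coverage=0.0)
        traj_full = years.assign(esf_coverage=1.0)
        spec = DrawSpec(n_draws=1, sample_effects=False, sample_baseline=False)
        result = es.run_simulation(
            panel, {"zero": traj_zero, "full": traj_full}, table, spec,
            strata=["nutritional"],
        )
        rr = es.scenario_ratio(result, "zero", "full", 2030, "nutritional")
        assert rr["ratio"] == pytest.approx(1 / 0.48)


class TestExcessDeaths:
    def test_identical_scenarios_have_zero_excess(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        result = es.run_simulation(
            ext, trajs, effects, DrawSpec(n_draws=10, master_seed=6),
            strata=["acsc_total"],
        )
        ed = es.excess_deaths(result, "uhc", "uhc")
        assert ed["excess_deaths"] == 0.0

    def test_antisymmetry(self, sim_inputs, effects):
        ext, trajs = sim_inputs
        result = es.run_simulation(
            ext, trajs, effects, DrawSpec(n_draws=10, master_seed=6),
            strata=["acsc_total"],
        )
        ab = es.excess_deaths(result, "austerity", "status_quo")
        ba = es.excess_deaths(result, "status_quo", "austerity")
        assert ab["excess_deaths"] == pytest.approx(-ba["excess_deaths"])

    def test_direct_arithmetic_single_municipality(self):
        # one municipality, pop 100k, one year: rates 60 vs 50 -> 10 deaths
        table = flat_effects(rr_full=0.5, gamma=0.0)
        panel = single_muni_panel(rate=60.0, years=range(2010, 2031), coverage=0.0)
        yrs = pd.DataFrame({"muni_id": "T0000", "year": range(2017, 2031)})
        # coverage that multiplies the rate by 50/60 past the lag:
        # c * ln(0.5) = ln(5/6)  =>  c = ln(5/6)/ln(0.5)
        c = np.log(5 / 6) / np.log(0.5)
        spec = DrawSpec(n_draws=1, sample_effects=False, sample_baseline=False)
        result = es.run_simulation(
            panel,
            {"a": yrs.assign(esf_coverage=0.0), "b": yrs.assign(esf_coverage=c)},
            table,
            spec,
            anchor_years=(2010, 2016),
        )
        ed = es.excess_deaths(result, "a", "b", years=[2025])
        assert ed["excess_deaths"] == pytest.approx(10.0, rel=1e-6)
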