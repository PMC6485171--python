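"""End-to-end pipeline: cohort -> forecast -> scenarios -> simulation -> reports.

``run_pipeline`` executes every stage from a validated RunConfig and
(optionally) writes the tidy CSV outputs plus a machine-readable run
manifest; reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cohort import generate_full_cohort
from .config import (
    RunConfig,
    cohort_params_from_config,
    config_hash,
    effect_table_from_config,
)
from .effects import EffectSizeTable, RACE_STRATA
from .forecast import NationalCalibrationPath, forecast_panel
from .inequality import quintile_rate_difference, standardised_rate_ratio
from .panel import MunicipalPanel
from .scenarios import ScenarioSpec, apply_scenario, default_scenarios
from .simulate import (
    DrawSpec,
    SimulationResult,
    excess_deaths,
    run_simulation,
    scenario_ratio,
    summarize,
)

__all__ = ["PipelineBundle", "run_pipeline", "apply_variant"]

logger = logging.getLogger("esfsim")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineBundle:
    config: RunConfig
    panel: MunicipalPanel
    extended_panel: MunicipalPanel
    trajectories: Mapping[str, pd.DataFrame]
    effects: EffectSizeTable
    result: SimulationResult
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    quintile_differences: pd.DataFrame | None
    srr_series: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)

    def headline(self) -> dict[str, float]:
        """Scalar headline outputs used by the sensitivity harness."""
        out: dict[str, float] = {}
        r = self.result
        for scen in ("austerity", "austerity_mmp_end", "uhc"):
            if scen in r.scenarios:
                rr = scenario_ratio(r, scen, "status_quo", 2030)
                out[f"ratio_2030_{scen}"] = rr["ratio"]
                ed = excess_deaths(r, scen, "status_quo")
                out[f"excess_deaths_{scen}"] = ed["excess_deaths"]
        if r.conc_index is not None and "austerity_mmp_end" in r.scenarios:
            ca = np.abs(r.conc_index_draws("austerity_mmp_end", 2030, "acsc_total"))
            cb = np.abs(r.conc_index_draws("status_quo", 2030, "acsc_total"))
            out["conc_index_change_pct_2030"] = float(
                np.mean((ca / cb - 1.0) * 100.0)
            )
        if set(RACE_STRATA).issubset(r.strata) and "austerity_mmp_end" in r.scenarios:
            for scen in ("austerity", "austerity_mmp_end"):
                sa = standardised_rate_ratio(r, scen, 2030)
                sb = standardised_rate_ratio(r, "status_quo", 2030)
                out[f"srr_change_pct_2030_{scen}"] = (
                    sa["srr"] / sb["srr"] - 1.0
                ) * 100.0
        return out

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.extended_panel.to_csv(out / "panel_extended.csv")
        traj = pd.concat(
            [t.assign(scenario=name) for name, t in self.trajectories.items()],
            ignore_index=True,
        )[["muni_id", "year", "scenario", "esf_coverage"]]
        traj.to_csv(out / "coverage_trajectories.csv", index=False, float_format=_FLOAT_FMT)
        self.summary.to_csv(out / "rate_summaries.csv", index=False, float_format=_FLOAT_FMT)
        self.comparisons.to_csv(out / "scenario_comparisons.csv", index=False, float_format=_FLOAT_FMT)
        if self.quintile_differences is not None:
            self.quintile_differences.to_csv(
                out / "quintile_rate_differences.csv", index=False, float_format=_FLOAT_FMT
            )
        if self.srr_series is not None:
            self.srr_series.to_csv(out / "srr_series.csv", index=False, float_format=_FLOAT_FMT)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
        logger.info("wrote outputs to %s", out)


def _scenario_specs(config: RunConfig) -> dict[str, ScenarioSpec]:
    sc = config.scenarios
    return default_scenarios(
        severity=sc.severity,
        mmp_termination_year=sc.mmp_termination_year,
        anchors=sc.decline_anchors,
    )


def run_pipeline(
    config: RunConfig, write: bool = True, panel: MunicipalPanel | None = None
) -> PipelineBundle:
    """Execute the full pipeline described by ``config``.

    ``panel`` overrides the configured panel source; the sensitivity
    harness uses this to analyse one fixed cohort under variant settings.
    """
    effects = effect_table_from_config(config)

    logger.info("stage 1/5: panel")
    if panel is not None:
        pass
    elif config.panel_path is not None:
        panel = MunicipalPanel.read_csv(config.panel_path)
    else:
        panel = generate_full_cohort(cohort_params_from_config(config))

    logger.info("stage 2/5: covariate forecast to %d", config.horizon)
    poverty_path = None
    if config.calibration.poverty_path:
        poverty_path = NationalCalibrationPath(
            "poverty_rate", dict(config.calibration.poverty_path)
        )
    extended = forecast_panel(panel, config.horizon, poverty_path)

    logger.info("stage 3/5: scenario trajectories")
    specs = _scenario_specs(config)
    last_obs = int(panel.years.max())
    trajectories = {
        name: apply_scenario(
            extended,
            spec,
            start_year=last_obs + 1,
            end_year=config.horizon,
            base_year=last_obs,
        )
        for name, spec in specs.items()
    }

    if config.calibration.observed_series:
        from .validation import ObservedSeries, calibrate_secular_trend
        from dataclasses import replace as _replace

        series = ObservedSeries(
            dict(config.calibration.observed_series),
            config.calibration.undernotification,
        )
        new_strata = dict(effects.strata)
        for stratum in config.calibration.calibrate_strata:
            gamma = calibrate_secular_trend(
                extended, effects, stratum, series,
                anchor_years=tuple(config.anchor_years),
                parameterization=config.parameterization,
            )
            logger.info("calibrated gamma[%s] = %.5f", stratum, gamma)
            new_strata[stratum] = _replace(new_strata[stratum], gamma=gamma)
        effects = _replace(effects, strata=new_strata)

    logger.info("stage 4/5: Monte Carlo (%d draws)", config.draws.n_draws)
    spec = DrawSpec(
        n_draws=config.draws.n_draws,
        master_seed=config.seed,
        sample_effects=config.draws.sample_effects,
        sample_baseline=config.draws.sample_baseline,
        rr_scale=config.draws.rr_scale,
    )
    result = run_simulation(
        extended,
        trajectories,
        effects,
        spec,
        strata=tuple(config.strata),
        anchor_years=tuple(config.anchor_years),
        years=(2010, config.horizon),
        parameterization=config.parameterization,
    )

    logger.info("stage 5/5: summaries")
    summary = summarize(result)
    comp_rows = []
    for scen in result.scenarios:
        if scen == "status_quo":
            continue
        for year in (2020, 2030):
            for stratum in result.strata:
                rr = scenario_ratio(result, scen, "status_quo", year, stratum)
                ed = excess_deaths(result, scen, "status_quo", stratum=stratum)
                comp_rows.append(
                    {
                        "scenario": scen,
                        "reference": "status_quo",
                        "year": year,
                        "stratum": stratum,
                        "rate_ratio": rr["ratio"],
                        "rr_ci_lo": rr["ci_lo"],
                        "rr_ci_hi": rr["ci_hi"],
                        "excess_deaths_2017_on": ed["excess_deaths"],
                        "ed_ci_lo": ed["ci_lo"],
                        "ed_ci_hi": ed["ci_hi"],
                    }
                )
    comparisons = pd.DataFrame(comp_rows)

    quintile_df = None
    if result.quintile_mean_rates is not None:
        frames = []
        for scen in ("austerity", "austerity_mmp_end"):
            if scen in result.scenarios:
                frames.append(
                    quintile_rate_difference(result, scen, "status_quo", 2030)
                )
        if frames:
            quintile_df = pd.concat(frames, ignore_index=True)

    srr_df = None
    if set(RACE_STRATA).issubset(result.strata):
        rows = []
        for scen in result.scenarios:
            for year in result.years:
                s = standardised_rate_ratio(result, scen, int(year))
                rows.append({"scenario": scen, "year": int(year), **s})
        srr_df = pd.DataFrame(rows)

    manifest = {
        "esfsim_version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_draws": config.draws.n_draws,
        "n_municipalities": panel.n_municipalities,
        "scenarios": list(result.scenarios),
        "strata": list(result.strata),
    }
    bundle = PipelineBundle(
        config=config,
        panel=panel,
        extended_panel=extended,
        trajectories=trajectories,
        effects=effects,
        result=result,
        summary=summary,
        comparisons=comparisons,
        quintile_differences=quintile_df,
        srr_series=srr_df,
        manifest=manifest,
    )
    if write:
        bundle.write(config.out_dir)
    return bundle


def apply_variant(config: RunConfig, axis: str, value) -> RunConfig:
    """A deep-copied config with one sensitivity-axis setting applied."""
    cfg = config.model_copy(deep=True)
    if axis == "decline_magnitude":
        cfg.scenarios.severity = config.scenarios.severity * float(value)
    elif axis == "duration_effect":
        if isinstance(value, (tuple, list)):
            kind, lag = value
            cfg.parameterization = str(kind)
            cfg.effects.duration_lag_years = int(lag)
        else:
            cfg.effects.duration_lag_years = int(value)
    elif axis == "poverty_stratified_effect":
        cfg.effects.poverty_multipliers = [float(v) for v in value]
    elif axis == "recession_path":
        cfg.calibration.poverty_path = {int(k): float(v) for k, v in value.items()}
    elif axis == "secular_trend":
        # additive shift of every stratum's gamma
        from .config import StratumEffectsConfig, CIConfig
        from .effects import default_effect_table

        base = effect_table_from_config(config)
        shifted = base.with_gamma_shift(float(value))
        cfg.effects.strata = {
            name: StratumEffectsConfig(
                rr_full=CIConfig(
                    point=se.rr_full.point, lo=se.rr_full.lo, hi=se.rr_full.hi
                ),
                covariates={
                    k: CIConfig(point=v.point, lo=v.lo, hi=v.hi)
                    for k, v in se.covariates.items()
                },
                gamma=se.gamma,
                baseline_rate=se.baseline_rate,
            )
            for name, se in shifted.strata.items()
        }
    else:
        raise ValueError(f"unknown sensitivity axis {axis!r}")
    return cfg
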