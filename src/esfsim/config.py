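"""Run configuration: schema, defaults, loading and conversion.

The YAML config mirrors the pipeline stages: a panel source (either a
CSV path or synthetic-cohort parameters, exactly one), the effect-size
table, scenario settings, Monte Carlo draw settings and the
calibration/validation inputs.  Unknown keys are rejected so typos fail
loudly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .cohort import CohortParams, CovariateSpec, default_covariate_specs
from .effects import (
    ALL_STRATA,
    EffectSizeTable,
    RateRatio,
    StratumEffects,
    default_effect_table,
)

__all__ = [
    "RunConfig",
    "load_config",
    "default_config",
    "effect_table_from_config",
    "cohort_params_from_config",
    "config_hash",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CIConfig(_Strict):
    point: float
    lo: float | None = None
    hi: float | None = None


class StratumEffectsConfig(_Strict):
    rr_full: CIConfig
    covariates: dict[str, CIConfig] | None = None  # None -> package defaults
    gamma: float = -0.022
    baseline_rate: float = 100.0


class EffectsConfig(_Strict):
    strata: dict[str, StratumEffectsConfig] | None = None
    duration_lag_years: int = 4
    poverty_multipliers: list[float] = Field(
        default_factory=lambda: [1.0, 1.0, 1.0, 1.0, 1.0]
    )

    @model_validator(mode="after")
    def _check(self):
        if len(self.poverty_multipliers) != 5:
            raise ValueError("poverty_multipliers needs exactly 5 entries")
        for name, se in (self.strata or {}).items():
            for label, ci in [("rr_full", se.rr_full)] + [
                (k, v) for k, v in (se.covariates or {}).items()
            ]:
                lo = ci.lo if ci.lo is not None else ci.point
                hi = ci.hi if ci.hi is not None else ci.point
                if not (0 < lo <= ci.point <= hi):
                    raise ValueError(
                        f"stratum {name!r}, effect {label!r}: interval "
                        f"({ci.lo}, {ci.hi}) does not bracket point {ci.point}"
                    )
        return self


class CohortConfig(_Strict):
    n_municipalities: int = 500
    year_start: int = 2000
    year_end: int = 2016
    coverage_mean: float = 0.804
    coverage_sd: float = 0.235
    mmp_start_year: int = 2013
    mmp_strength: float = 2.0
    mmp_scale: float = 0.25
    alpha_sd: float = 0.3
    alpha_poverty_slope: float = 1.0


class ScenariosConfig(_Strict):
    decline_anchors: dict[int, float] = Field(
        default_factory=lambda: {2016: 1.0, 2020: 66.5 / 80.4, 2030: 37.8 / 80.4}
    )
    severity: float = 1.0
    mmp_termination_year: int = 2019
    uhc_target_year: int = 2030


class DrawsConfig(_Strict):
    n_draws: int = 500
    sample_effects: bool = True
    sample_baseline: bool = True
    rr_scale: Literal["log", "natural"] = "log"


class CalibrationConfig(_Strict):
    observed_series: dict[int, float] | None = None
    undernotification: float = 1.0
    calibrate_strata: list[str] = Field(default_factory=lambda: ["acsc_total"])
    poverty_path: dict[int, float] | None = Field(
        default_factory=lambda: {2015: 0.138, 2020: 0.184, 2030: 0.120}
    )


class RunConfig(_Strict):
    panel_path: str | None = None
    cohort: CohortConfig | None = None
    effects: EffectsConfig = Field(default_factory=EffectsConfig)
    scenarios: ScenariosConfig = Field(default_factory=ScenariosConfig)
    draws: DrawsConfig = Field(default_factory=DrawsConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    strata: list[str] = Field(default_factory=lambda: list(ALL_STRATA))
    parameterization: Literal["continuous", "categorical"] = "continuous"
    anchor_years: tuple[int, int] = (2010, 2016)
    horizon: int = 2030
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _exclusive_source(self):
        if (self.panel_path is None) == (self.cohort is None):
            raise ValueError(
                "exactly one of panel_path and cohort must be configured"
            )
        if self.panel_path is not None and not Path(self.panel_path).exists():
            raise ValueError(f"panel file not found: {self.panel_path}")
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def default_config(**overrides) -> RunConfig:
    """Desk-scale default configuration (synthetic cohort source)."""
    cfg = RunConfig(cohort=CohortConfig())
    for key, value in overrides.items():
        setattr(cfg, key, value)
    return cfg


def effect_table_from_config(config: RunConfig) -> EffectSizeTable:
    """Materialise the EffectSizeTable, falling back to package defaults."""
    base = default_effect_table()
    ecfg = config.effects
    if ecfg.strata is None:
        strata = dict(base.strata)
    else:
        strata = {}
        for name, se in ecfg.strata.items():
            if se.covariates is None:
                cov = base.strata.get(name, next(iter(base.strata.values()))).covariates
            else:
                cov = {
                    k: RateRatio(v.point, v.lo, v.hi)
                    for k, v in se.covariates.items()
                }
            strata[name] = StratumEffects(
                rr_full=RateRatio(se.rr_full.point, se.rr_full.lo, se.rr_full.hi),
                covariates=cov,
                gamma=se.gamma,
                baseline_rate=se.baseline_rate,
            )
    return EffectSizeTable(
        strata=strata,
        duration_lag_years=ecfg.duration_lag_years,
        poverty_multipliers=tuple(ecfg.poverty_multipliers),
    )


def cohort_params_from_config(config: RunConfig) -> CohortParams:
    c = config.cohort
    if c is None:
        raise ValueError("config has no cohort section")
    return CohortParams(
        n_municipalities=c.n_municipalities,
        year_start=c.year_start,
        year_end=c.year_end,
        master_seed=config.seed,
        covariates=default_covariate_specs(),
        coverage_mean=c.coverage_mean,
        coverage_sd=c.coverage_sd,
        mmp_start_year=c.mmp_start_year,
        mmp_strength=c.mmp_strength,
        mmp_scale=c.mmp_scale,
        alpha_sd=c.alpha_sd,
        alpha_poverty_slope=c.alpha_poverty_slope,
        true_effects=effect_table_from_config(config),
    )


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
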