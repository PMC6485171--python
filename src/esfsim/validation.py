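"""Calibration, internal/external validation and the sensitivity harness.

* secular-trend calibration: refit the per-year log-rate drift gamma so
  the model's predicted national mean rate tracks an observed series;
* internal validation: refit the fixed-effects Poisson regression on a
  simulated panel and check that the coefficients equal the inputs;
* external validation: regress observed rates on predicted ones;
* sensitivity harness: rerun the pipeline over variant settings of the
  model's structural choices and collect the headline outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import EffectSizeTable
from .fepoisson import FEPoissonResult, fit_fe_poisson
from .model import (
    BASE_YEAR,
    coverage_duration,
    coverage_effect,
    estimate_fixed_effects,
    _coverage_matrix,
    _linear_predictor,
    _require_coverage,
    _stack_covariates,
)
from .panel import MunicipalPanel

__all__ = [
    "ObservedSeries",
    "ValidationReport",
    "SensitivityGrid",
    "calibrate_secular_trend",
    "internal_validation",
    "external_validation",
    "run_sensitivity",
    "simulate_outcome_panel",
]

_SENSITIVITY_AXES = (
    "decline_magnitude",
    "duration_effect",
    "poverty_stratified_effect",
    "recession_path",
    "secular_trend",
)


@dataclass(frozen=True)
class ObservedSeries:
    """Observed national mean rates (year -> rate per 100,000).

    ``undernotification`` is a multiplicative correction (>= 1) applied to
    the observed rates before comparison with model output, standing in
    for incomplete vital registration.
    """

    rates: Mapping[int, float]
    undernotification: float = 1.0

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("observed rates must be non-negative")
        if self.undernotification < 1.0:
            raise ValueError("undernotification factor must be >= 1")

    def corrected(self) -> dict[int, float]:
        return {y: r * self.undernotification for y, r in self.rates.items()}


@dataclass
class ValidationReport:
    slope: float = np.nan
    intercept: float = np.nan
    r_squared: float = np.nan
    frac_within_ci: float = np.nan
    max_coef_deviation: float = np.nan
    coef_table: pd.DataFrame | None = None
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# secular-trend calibration
# ---------------------------------------------------------------------------


def _national_mean_rates(
    panel: MunicipalPanel,
    effects: EffectSizeTable,
    stratum: str,
    years: list[int],
    anchor_years: tuple[int, int],
    parameterization: str,
) -> np.ndarray:
    """Population-weighted national mean predicted rate for given years."""
    alphas = estimate_fixed_effects(
        panel, effects, stratum, anchor_years, parameterization
    )
    covw = _coverage_matrix(panel, None)
    _require_coverage(covw, years)
    dur = coverage_duration(np.nan_to_num(covw.values, nan=0.0))
    sel = [list(covw.columns).index(y) for y in years]
    sub = panel.subset_years(min(years), max(years))
    X, index = _stack_covariates(sub, years)
    se = effects[stratum]
    eta = _linear_predictor(X, np.array(years), se, panel.covariates)
    ceff = coverage_effect(
        covw.values[:, sel], dur[:, sel], effects, stratum, parameterization
    )
    rates = np.exp(alphas.reindex(index).values[:, None] + eta + ceff)
    pyw = (
        pd.DataFrame(
            {
                "muni_id": sub.data["muni_id"],
                "year": sub.data["year"],
                "v": sub.person_years(stratum),
            }
        )
        .pivot(index="muni_id", columns="year", values="v")
        .reindex(index=index, columns=years)
        .values
    )
    return (rates * pyw).sum(axis=0) / pyw.sum(axis=0)


def calibrate_secular_trend(
    panel: MunicipalPanel,
    effects: EffectSizeTable,
    stratum: str,
    observed: ObservedSeries,
    window: tuple[int, int] = (2010, 2015),
    anchor_years: tuple[int, int] = (2010, 2016),
    parameterization: str = "continuous",
) -> float:
    """Secular-trend coefficient calibrated to an observed national series.

    The calibrated gamma minimises, over the window, the squared log-scale
    discrepancy between the predicted national mean rate and the
    (undernotification-corrected) observed series up to a free level
    shift: the level of the model is pinned separately by anchoring the
    fixed effects on observed death counts, so calibration adjusts only
    the time slope.  In closed form the update is the OLS slope of
    ln(observed) - ln(predicted at the current gamma) on calendar year,
    added to the current gamma; the procedure is exactly idempotent.
    """
    corrected = observed.corrected()
    years = sorted(
        y for y in corrected if window[0] <= y <= window[1] and y in set(panel.years)
    )
    if len(years) < 2:
        raise ValueError("need at least two observed years inside the window")
    obs = np.array([corrected[y] for y in years])
    if (obs <= 0).any():
        raise ValueError("observed rates must be strictly positive after correction")
    pred = _national_mean_rates(
        panel, effects, stratum, years, anchor_years, parameterization
    )
    resid = np.log(obs) - np.log(pred)
    slope = np.polyfit(np.asarray(years, dtype=float), resid, 1)[0]
    return float(effects[stratum].gamma + slope)


# ---------------------------------------------------------------------------
# internal validation
# ---------------------------------------------------------------------------


def simulate_outcome_panel(
    panel: MunicipalPanel,
    trajectory: pd.DataFrame | None,
    effects: EffectSizeTable,
    alphas: pd.Series,
    stratum: str,
    years: tuple[int, int] = (2017, 2030),
    rng: np.random.Generator | None = None,
    parameterization: str = "continuous",
) -> pd.DataFrame:
    """Deaths simulated from the model along a coverage trajectory.

    Returns a tidy frame (muni_id, year, deaths, person_years, coverage,
    consolidated coverage term, covariates) over ``years``; deaths are
    Poisson draws when ``rng`` is given, expectations otherwise.
    """
    lo, hi = years
    covw = _coverage_matrix(panel, trajectory)
    year_list = [int(y) for y in covw.columns if lo <= y <= hi]
    _require_coverage(covw, year_list)
    dur = coverage_duration(np.nan_to_num(covw.values, nan=0.0))
    sel = [list(covw.columns).index(y) for y in year_list]
    sub = panel.subset_years(lo, hi)
    X, index = _stack_covariates(sub, year_list)
    se = effects[stratum]
    eta = _linear_predictor(X, np.array(year_list), se, panel.covariates)
    cov_m = covw.values[:, sel]
    dur_m = dur[:, sel]
    ceff = coverage_effect(cov_m, dur_m, effects, stratum, parameterization)
    rates = np.exp(alphas.reindex(index).values[:, None] + eta + ceff)
    pyw = (
        pd.DataFrame(
            {
                "muni_id": sub.data["muni_id"],
                "year": sub.data["year"],
                "v": sub.person_years(stratum),
            }
        )
        .pivot(index="muni_id", columns="year", values="v")
        .reindex(index=index, columns=year_list)
        .values
    )
    mu = rates * pyw / 1e5
    deaths = mu if rng is None else rng.poisson(mu).astype(float)
    lag = effects.duration_lag_years
    consolidated = cov_m * np.minimum(dur_m / float(lag), 1.0)
    n, T = mu.shape
    out = pd.DataFrame(
        {
            "muni_id": np.repeat(index.to_numpy(), T),
            "year": np.tile(year_list, n),
            "deaths": deaths.reshape(-1),
            "person_years": pyw.reshape(-1),
            "esf_consolidated": consolidated.reshape(-1),
        }
    )
    for j, name in enumerate(panel.covariates):
        out[name] = X[:, :, j].reshape(-1)
    return out


def internal_validation(
    sim_panel: pd.DataFrame,
    effects: EffectSizeTable,
    stratum: str,
    covariates: Iterable[str] | None = None,
) -> ValidationReport:
    """Refit the fixed-effects Poisson model on simulated data.

    The regression includes the municipality intercepts, the model
    covariates, the linear time trend and the consolidated-coverage term;
    the report carries the maximum absolute deviation of fitted log rate
    ratios from the inputs and per-coefficient Wald intervals.
    """
    se = effects[stratum]
    cov_names = list(covariates) if covariates is not None else list(se.covariates)
    X = sim_panel[cov_names].copy()
    X["time"] = sim_panel["year"].astype(float) - BASE_YEAR
    X["esf_consolidated"] = sim_panel["esf_consolidated"]
    truth = pd.Series(
        {name: se.covariates[name].ln for name in cov_names}
        | {"time": se.gamma, "esf_consolidated": se.rr_full.ln}
    )
    flags = []
    try:
        fit: FEPoissonResult = fit_fe_poisson(
            sim_panel["deaths"],
            X,
            sim_panel["muni_id"],
            sim_panel["person_years"] / 1e5,
        )
    except ValueError as err:
        return ValidationReport(flags=[f"fit failed: {err}"])
    if not fit.converged:
        flags.append("fixed-effects Poisson fit did not converge")
    if fit.dropped_groups:
        flags.append(f"dropped {len(fit.dropped_groups)} all-zero municipalities")
    ci = fit.conf_int()
    table = pd.DataFrame(
        {
            "true": truth,
            "fitted": fit.params,
            "se": fit.bse,
            "ci_lo": ci["lo"],
            "ci_hi": ci["hi"],
        }
    )
    table["deviation"] = table["fitted"] - table["true"]
    table["inside_ci"] = (table["true"] >= table["ci_lo"]) & (
        table["true"] <= table["ci_hi"]
    )
    return ValidationReport(
        max_coef_deviation=float(table["deviation"].abs().max()),
        coef_table=table,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# external validation
# ---------------------------------------------------------------------------


def external_validation(
    predicted: pd.DataFrame,
    observed: ObservedSeries,
) -> ValidationReport:
    """OLS of observed national rates on predicted ones.

    ``predicted`` has columns year, rate and optionally ci_lo/ci_hi; the
    report carries slope, intercept, R^2 and the fraction of observed
    points inside the predicted 95% credible band.
    """
    import statsmodels.api as sm

    corrected = observed.corrected()
    pred = predicted.set_index("year")
    years = [y for y in corrected if y in pred.index]
    flags = []
    if len(years) < 3:
        flags.append("fewer than 3 overlapping years: R^2 undefined")
        return ValidationReport(flags=flags)
    obs = np.array([corrected[y] for y in years])
    x = pred.loc[years, "rate"].to_numpy(dtype=float)
    fit = sm.OLS(obs, sm.add_constant(x)).fit()
    frac = np.nan
    if {"ci_lo", "ci_hi"}.issubset(pred.columns):
        lo = pred.loc[years, "ci_lo"].to_numpy(dtype=float)
        hi = pred.loc[years, "ci_hi"].to_numpy(dtype=float)
        frac = float(np.mean((obs >= lo) & (obs <= hi)))
    return ValidationReport(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        frac_within_ci=frac,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# sensitivity harness
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityGrid:
    """Variants along one sensitivity axis.

    ``variants`` maps a variant label to the axis-specific setting:
    decline_magnitude -> severity multiplier on the decline path;
    duration_effect -> duration lag in years or ("categorical", lag);
    poverty_stratified_effect -> five per-quintile effect multipliers;
    recession_path -> year->poverty calibration targets;
    secular_trend -> additive shift of gamma (per year).
    """

    axis: str
    variants: Mapping[str, object]

    def __post_init__(self) -> None:
        if self.axis not in _SENSITIVITY_AXES:
            raise ValueError(
                f"unknown sensitivity axis {self.axis!r}; choose from "
                f"{_SENSITIVITY_AXES}"
            )
        if len(self.variants) < 2:
            raise ValueError("a sensitivity grid needs at least 2 variants")


def run_sensitivity(
    config,
    grid: SensitivityGrid,
    runner: Callable | None = None,
) -> pd.DataFrame:
    """Rerun the pipeline per variant (shared seed) and tabulate headlines.

    Returns one row per variant with the 2030 austerity/status-quo rate
    ratio, 2017-2030 excess deaths for both austerity scenarios versus the
    status quo, the 2030 concentration-index change and the 2030
    black/white SRR change.  The municipal cohort is built once from the
    base config and shared across variants (the axes vary the analysis,
    not the data).  Failed variants are reported with an error column,
    not dropped.  ``runner`` defaults to the full pipeline and is
    injectable for testing.
    """
    from .cohort import generate_full_cohort
    from .config import cohort_params_from_config
    from .pipeline import apply_variant, run_pipeline

    if config.panel_path is not None:
        panel = MunicipalPanel.read_csv(config.panel_path)
    else:
        panel = generate_full_cohort(cohort_params_from_config(config))

    rows = []
    for label, value in grid.variants.items():
        variant_config = apply_variant(config, grid.axis, value)
        try:
            bundle = (runner or run_pipeline)(
                variant_config, write=False, panel=panel
            )
            rows.append({"variant": label, "error": "", **bundle.headline()})
        except Exception as err:  # report, never silently drop
            rows.append({"variant": label, "error": str(err)})
    out = pd.DataFrame(rows)
    out.insert(0, "axis", grid.axis)
    return out
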