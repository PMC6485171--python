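"""Fixed-effects log-linear ACSC mortality model.

The expected mortality rate (deaths per 100,000 person-years) of
municipality *i* in year *t* under outcome stratum *s* is

    rate = exp( alpha_i + gamma * (t - 2010) + sum_k ln(beta_k) * x_ikt
                + coverage_effect(c_it, d_it) )

where ``alpha_i`` is a municipality fixed effect, ``gamma`` the secular
trend, ``beta_k`` the covariate rate ratios, ``c_it`` the ESF coverage
fraction and ``d_it`` the number of consecutive years the programme has
been active.  The coverage effect interpolates the full-coverage rate
ratio: ``c * min(d/L, 1) * ln(rr_full)`` under the default continuous
parameterization.

The module exposes both the plain functions used throughout the package
and a statsmodels-style :class:`ACSCMortalityModel` /
:class:`ACSCMortalityResults` pair.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import EffectSizeTable, StratumEffects, default_effect_table
from .panel import MunicipalPanel

__all__ = [
    "coverage_duration",
    "coverage_effect",
    "expected_rate",
    "estimate_fixed_effects",
    "predict_panel",
    "ACSCMortalityModel",
    "ACSCMortalityResults",
]

BASE_YEAR = 2010  # year at which the secular trend is zero

_PARAMETERIZATIONS = ("continuous", "categorical")


# ---------------------------------------------------------------------------
# coverage effect
# ---------------------------------------------------------------------------


def coverage_duration(coverage: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """Years of uninterrupted programme presence along coverage histories.

    ``coverage`` is (n_munis, n_years) in chronological order.  Duration
    counts consecutive years with coverage above ``threshold`` and resets
    to zero on interruption; the first active year has duration 1.
    """
    cov = np.asarray(coverage, dtype=float)
    if cov.ndim == 1:
        cov = cov[None, :]
    duration = np.zeros(cov.shape[0])
    out = np.empty_like(cov)
    for j in range(cov.shape[1]):
        active = cov[:, j] > threshold
        duration = np.where(active, duration + 1.0, 0.0)
        out[:, j] = duration
    return out


def coverage_effect(
    coverage,
    duration,
    table: EffectSizeTable,
    stratum: str,
    parameterization: str = "continuous",
    quintile=None,
):
    """Log-rate contribution of ESF coverage.

    ``duration`` is years of sustained coverage; the ramp min(duration/L, 1)
    phases the full effect in over the duration lag L.  With
    ``rr_full <= 1`` the contribution is always <= 0.
    """
    if parameterization not in _PARAMETERIZATIONS:
        raise ValueError(
            f"unknown parameterization {parameterization!r}; "
            f"choose from {_PARAMETERIZATIONS}"
        )
    se = table[stratum]
    lnrr = se.rr_full.ln
    if quintile is not None:
        mult = np.asarray(table.poverty_multipliers)[np.asarray(quintile) - 1]
        lnrr = lnrr * mult
    cov = np.asarray(coverage, dtype=float)
    dur = np.asarray(duration, dtype=float)
    if (dur < 0).any():
        raise ValueError("duration must be non-negative")
    ramp = np.minimum(dur / float(table.duration_lag_years), 1.0)
    if parameterization == "continuous":
        out = cov * ramp * lnrr
    else:
        # coverage-duration classes: none (< 70% coverage), consolidating
        # (>= 70% but for fewer years than the lag), consolidated (>= 70%
        # for >= lag years).  The consolidating class gets half the effect.
        consolidated = (cov >= 0.7) & (ramp >= 1.0)
        consolidating = (cov >= 0.7) & ~consolidated
        out = np.where(consolidated, lnrr, np.where(consolidating, 0.5 * lnrr, 0.0))
    return out if np.ndim(coverage) or np.ndim(duration) else float(out)


# ---------------------------------------------------------------------------
# expected rates
# ---------------------------------------------------------------------------


def _covariate_terms(covariates: Mapping, se: StratumEffects, names: Iterable[str]):
    total = 0.0
    for name in names:
        if name not in covariates:
            raise KeyError(f"missing covariate {name!r} in model input")
        total = total + np.asarray(covariates[name], dtype=float) * se.covariates[name].ln
    return total


def expected_rate(
    covariates: Mapping,
    coverage,
    duration,
    alpha,
    table: EffectSizeTable,
    stratum: str,
    year,
    covariate_names: Iterable[str] | None = None,
    parameterization: str = "continuous",
    quintile=None,
):
    """Deterministic expected mortality rate per 100,000 person-years."""
    se = table[stratum]
    names = tuple(covariate_names) if covariate_names is not None else tuple(se.covariates)
    eta = (
        np.asarray(alpha, dtype=float)
        + se.gamma * (np.asarray(year, dtype=float) - BASE_YEAR)
        + _covariate_terms(covariates, se, names)
        + coverage_effect(coverage, duration, table, stratum, parameterization, quintile)
    )
    return np.exp(eta)


# ---------------------------------------------------------------------------
# array engine shared with the Monte Carlo module
# ---------------------------------------------------------------------------


def _stack_covariates(panel: MunicipalPanel, years) -> tuple[np.ndarray, pd.Index]:
    mats = []
    index = None
    for name in panel.covariates:
        wide = panel.pivot(name, years)
        if wide.isna().any().any():
            bad_years = wide.columns[wide.isna().any(axis=0)].tolist()
            raise ValueError(
                f"covariate {name!r} missing for years {bad_years[:5]}"
            )
        mats.append(wide.values)
        index = wide.index
    X = np.stack(mats, axis=-1)  # (n, T, k)
    return X, index


def _linear_predictor(
    X: np.ndarray,
    years: np.ndarray,
    se: StratumEffects,
    names: Iterable[str],
) -> np.ndarray:
    """gamma * (t - 2010) + sum_k ln(beta_k) x, shape (n, T)."""
    lnbeta = np.array(se.covariate_lnrr(names))
    return X @ lnbeta + se.gamma * (np.asarray(years, dtype=float) - BASE_YEAR)[None, :]


def _coverage_matrix(
    panel: MunicipalPanel, trajectory: pd.DataFrame | None
) -> pd.DataFrame:
    """Observed coverage overlaid with a scenario trajectory (wide, all years)."""
    wide = panel.pivot("esf_coverage")
    if trajectory is not None:
        traj = trajectory.pivot(index="muni_id", columns="year", values="esf_coverage")
        missing = wide.index.difference(traj.index)
        extra = traj.index.difference(wide.index)
        if len(extra):
            raise ValueError(
                f"trajectory has municipalities absent from the panel: {list(extra)[:5]}"
            )
        if len(missing) and traj.shape[0] != wide.shape[0]:
            raise ValueError(
                f"trajectory missing municipalities: {list(missing)[:5]}"
            )
        traj = traj.reindex(wide.index)
        for year in traj.columns:
            if year not in wide.columns:
                wide[year] = np.nan
            wide.loc[:, year] = traj[year].values
        wide = wide.reindex(columns=sorted(wide.columns))
    return wide


def _require_coverage(wide: pd.DataFrame, years) -> None:
    cols = [y for y in years if y in wide.columns]
    missing = [y for y in years if y not in wide.columns]
    if missing:
        raise ValueError(f"coverage undefined for years {missing[:5]}")
    block = wide[cols]
    if block.isna().any().any():
        bad = block.columns[block.isna().any(axis=0)].tolist()
        raise ValueError(f"coverage undefined for years {bad[:5]}")


# ---------------------------------------------------------------------------
# fixed-effect anchoring
# ---------------------------------------------------------------------------


def estimate_fixed_effects(
    panel: MunicipalPanel,
    table: EffectSizeTable,
    stratum: str,
    anchor_years: tuple[int, int] = (2010, 2016),
    parameterization: str = "continuous",
    deaths_override: np.ndarray | None = None,
    quintile=None,
) -> pd.Series:
    """Municipality log-rate intercepts anchored on observed deaths.

    alpha_i is chosen so the model's mean predicted log rate over the
    anchor window equals the mean observed log rate, with a +0.5
    continuity correction on zero-death years.  Municipalities whose
    observed deaths are all zero sit at the continuity-correction floor
    and are listed in ``result.attrs['degenerate']``.
    """
    lo, hi = anchor_years
    years = [y for y in panel.years if lo <= y <= hi]
    if not years:
        raise ValueError(f"panel has no years in anchor window {anchor_years}")
    covw = _coverage_matrix(panel, None)
    _require_coverage(covw, years)
    dur_all = coverage_duration(np.nan_to_num(covw.values, nan=0.0))
    sel = [list(covw.columns).index(y) for y in years]
    cov = covw.values[:, sel]
    dur = dur_all[:, sel]

    sub = panel.subset_years(lo, hi)
    X, index = _stack_covariates(sub, years)
    se = table[stratum]
    eta = _linear_predictor(X, np.array(years), se, panel.covariates)
    ceff = coverage_effect(cov, dur, table, stratum, parameterization, quintile)

    py = sub.person_years(stratum)
    deaths = (
        sub.deaths(stratum).to_numpy(dtype=float)
        if deaths_override is None
        else np.asarray(deaths_override, dtype=float)
    )
    pyw = (
        pd.DataFrame({"muni_id": sub.data["muni_id"], "year": sub.data["year"], "v": py})
        .pivot(index="muni_id", columns="year", values="v")
        .reindex(index=index, columns=years)
        .values
    )
    dw = (
        pd.DataFrame(
            {"muni_id": sub.data["muni_id"], "year": sub.data["year"], "v": deaths}
        )
        .pivot(index="muni_id", columns="year", values="v")
        .reindex(index=index, columns=years)
        .values
    )
    if (pyw <= 0).any():
        bad = index[(pyw <= 0).any(axis=1)]
        raise ValueError(f"zero person-years for municipalities {list(bad)[:5]}")
    corrected = np.where(dw == 0, 0.5, dw)
    log_obs = np.log(corrected / pyw * 1e5)
    alpha = (log_obs - eta - ceff).mean(axis=1)
    out = pd.Series(alpha, index=index, name=f"alpha_{stratum}")
    out.attrs["degenerate"] = list(index[(dw == 0).all(axis=1)])
    return out


# ---------------------------------------------------------------------------
# panel prediction
# ---------------------------------------------------------------------------


def predict_panel(
    panel: MunicipalPanel,
    trajectories: Mapping[str, pd.DataFrame],
    fixed_effects: Mapping[str, pd.Series],
    table: EffectSizeTable,
    strata: Iterable[str],
    years: tuple[int, int] = (2010, 2030),
    parameterization: str = "continuous",
    quintile=None,
) -> pd.DataFrame:
    """Tidy rate predictions per (municipality, year, scenario, stratum)."""
    lo, hi = years
    year_list = [y for y in panel.years if lo <= y <= hi]
    sub = panel.subset_years(lo, hi)
    X, index = _stack_covariates(sub, year_list)
    yr_arr = np.array(year_list)
    frames = []
    for scenario, traj in trajectories.items():
        covw = _coverage_matrix(panel, traj)
        _require_coverage(covw, year_list)
        dur_all = coverage_duration(np.nan_to_num(covw.values, nan=0.0))
        sel = [list(covw.columns).index(y) for y in year_list]
        cov = covw.values[:, sel]
        dur = dur_all[:, sel]
        for stratum in strata:
            se = table[stratum]
            alpha = fixed_effects[stratum].reindex(index)
            if alpha.isna().any():
                bad = index[alpha.isna()]
                raise ValueError(
                    f"missing fixed effects for municipalities {list(bad)[:5]}"
                )
            eta = _linear_predictor(X, yr_arr, se, panel.covariates)
            ceff = coverage_effect(cov, dur, table, stratum, parameterization, quintile)
            rates = np.exp(alpha.values[:, None] + eta + ceff)
            frame = pd.DataFrame(rates, index=index, columns=year_list)
            tidy = frame.reset_index().melt(
                id_vars="muni_id", var_name="year", value_name="rate"
            )
            tidy["scenario"] = scenario
            tidy["stratum"] = stratum
            frames.append(tidy)
    out = pd.concat(frames, ignore_index=True)
    return out[["muni_id", "year", "scenario", "stratum", "rate"]]


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class ACSCMortalityModel:
    """Fixed-effects log-linear mortality model for one outcome stratum.

    Parameters
    ----------
    panel : MunicipalPanel
        Panel with covariates for the prediction years and observed deaths
        over the anchor window.
    effects : EffectSizeTable, optional
        Effect sizes (rate ratios); defaults to the package table.
    stratum : str
        Outcome stratum, e.g. ``"acsc_total"``.
    anchor_years : (int, int)
        Window of observed deaths used to anchor the fixed effects.
    """

    def __init__(
        self,
        panel: MunicipalPanel,
        effects: EffectSizeTable | None = None,
        stratum: str = "acsc_total",
        anchor_years: tuple[int, int] = (2010, 2016),
        parameterization: str = "continuous",
    ) -> None:
        self.panel = panel
        self.effects = effects if effects is not None else default_effect_table()
        self.stratum = stratum
        self.anchor_years = anchor_years
        if parameterization not in _PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {parameterization!r}")
        self.parameterization = parameterization

    def fit(
        self,
        observed: Mapping[int, float] | None = None,
        calibration_window: tuple[int, int] = (2010, 2015),
        undernotification: float = 1.0,
    ) -> "ACSCMortalityResults":
        """Anchor fixed effects; optionally calibrate the secular trend.

        When ``observed`` (year -> national mean rate) is given, gamma is
        first re-fitted so predicted national rates track the observed
        series over ``calibration_window``.
        """
        effects = self.effects
        if observed is not None:
            from .validation import ObservedSeries, calibrate_secular_trend

            series = (
                observed
                if isinstance(observed, ObservedSeries)
                else ObservedSeries(dict(observed), undernotification)
            )
            gamma = calibrate_secular_trend(
                self.panel,
                effects,
                self.stratum,
                series,
                window=calibration_window,
                anchor_years=self.anchor_years,
                parameterization=self.parameterization,
            )
            effects = replace(
                effects,
                strata={
                    **effects.strata,
                    self.stratum: replace(effects.strata[self.stratum], gamma=gamma),
                },
            )
        alphas = estimate_fixed_effects(
            self.panel, effects, self.stratum, self.anchor_years, self.parameterization
        )
        return ACSCMortalityResults(self, effects, alphas)


class ACSCMortalityResults:
    """Fitted model state: effect sizes in use plus anchored fixed effects."""

    def __init__(
        self,
        model: ACSCMortalityModel,
        effects: EffectSizeTable,
        fixed_effects: pd.Series,
    ) -> None:
        self.model = model
        self.effects = effects
        self.fixed_effects = fixed_effects

    @property
    def stratum(self) -> str:
        return self.model.stratum

    @property
    def params(self) -> pd.Series:
        """Log rate ratios, secular trend and coverage effect in one Series."""
        se = self.effects[self.stratum]
        data = {"gamma": se.gamma, "ln_rr_full_coverage": se.rr_full.ln}
        for name in self.model.panel.covariates:
            data[f"ln_rr_{name}"] = se.covariates[name].ln
        return pd.Series(data)

    def predict(
        self,
        trajectory: pd.DataFrame | None = None,
        years: tuple[int, int] = (2010, 2030),
    ) -> pd.DataFrame:
        """Deterministic rate predictions (tidy muni_id/year/rate frame)."""
        preds = predict_panel(
            self.model.panel,
            {"_": trajectory},
            {self.stratum: self.fixed_effects},
            self.effects,
            [self.stratum],
            years=years,
            parameterization=self.model.parameterization,
        )
        return preds.drop(columns=["scenario", "stratum"])

    def simulate(self, trajectories: Mapping[str, pd.DataFrame], draw_spec=None, **kw):
        """Monte Carlo simulation over scenarios for this stratum."""
        from .simulate import DrawSpec, run_simulation

        spec = draw_spec if draw_spec is not None else DrawSpec()
        return run_simulation(
            self.model.panel,
            trajectories,
            self.effects,
            spec,
            strata=[self.stratum],
            anchor_years=self.model.anchor_years,
            parameterization=self.model.parameterization,
            **kw,
        )

    def summary(self) -> str:
        se = self.effects[self.stratum]
        lines = [
            "ACSC mortality model results",
            "=" * 64,
            f"Outcome stratum:        {self.stratum}",
            f"Municipalities:         {self.model.panel.n_municipalities}",
            f"Anchor window:          {self.model.anchor_years[0]}-{self.model.anchor_years[1]}",
            f"Parameterization:       {self.model.parameterization}",
            f"Duration lag (years):   {self.effects.duration_lag_years}",
            f"Secular trend gamma:    {se.gamma:+.5f} per year",
            "-" * 64,
            f"{'term':<26}{'RR':>9}{'95% lo':>9}{'95% hi':>9}{'ln RR':>10}",
        ]
        rows = [("full ESF coverage", se.rr_full)] + [
            (name, rr) for name, rr in se.covariates.items()
        ]
        for name, rr in rows:
            lines.append(
                f"{name:<26}{rr.point:>9.3f}{rr.lo:>9.3f}{rr.hi:>9.3f}{rr.ln:>10.4f}"
            )
        fe = self.fixed_effects
        q = fe.quantile([0.05, 0.5, 0.95])
        lines += [
            "-" * 64,
            "Fixed effects alpha_i (log rate per 100,000):",
            f"  median {q[0.5]:.3f}   5% {q[0.05]:.3f}   95% {q[0.95]:.3f}",
            f"  implied median baseline rate: {math.exp(q[0.5]):.1f} per 100,000",
        ]
        degenerate = fe.attrs.get("degenerate", [])
        if degenerate:
            lines.append(f"  zero-death municipalities at floor: {len(degenerate)}")
        return "\n".join(lines)
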