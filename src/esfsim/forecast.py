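"""Covariate extrapolation from municipal 2000-2010 trends.

Socioeconomic and healthcare covariates are projected from 2011 to 2030
with per-municipality exponential trends fitted by OLS on the log scale
over the 2000-2010 decade, then optionally recalibrated so the national
population-weighted mean of a covariate (poverty during the recession
years) tracks an externally supplied path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import COVARIATE_META
from .panel import MunicipalPanel

__all__ = [
    "DecayTrend",
    "NationalCalibrationPath",
    "fit_decay_trend",
    "extrapolate",
    "calibrate_national",
    "forecast_panel",
]


@dataclass(frozen=True)
class DecayTrend:
    """Exponential trend value(t) = floor + (level_2010 - floor) e^{-lam (t-2010)}.

    ``lam`` > 0 is decay, < 0 growth.  ``degenerate`` flags series that
    could not be fitted (all at the floor); those extrapolate flat.
    """

    level_2010: float
    lam: float
    floor: float = 0.0
    cap: float | None = None
    muni_id: str | None = None
    name: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.cap is not None and self.cap < self.floor:
            raise ValueError("cap must be >= floor")


@dataclass(frozen=True)
class NationalCalibrationPath:
    """Year -> target national population-weighted mean for one covariate."""

    name: str
    targets: Mapping[int, float]

    def __post_init__(self) -> None:
        for year, value in self.targets.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"calibration target {value} for {year} outside [0, 1]"
                )

    def interpolated(self, years: Iterable[int]) -> dict[int, float]:
        """Linear interpolation of the anchor targets onto ``years``."""
        ys = sorted(self.targets)
        vals = [self.targets[y] for y in ys]
        out = {}
        for year in years:
            if ys[0] <= year <= ys[-1]:
                out[year] = float(np.interp(year, ys, vals))
        return out


def fit_decay_trend(
    years: Iterable[int],
    values: Iterable[float],
    floor: float = 0.0,
    cap: float | None = None,
    muni_id: str | None = None,
    name: str | None = None,
) -> DecayTrend:
    """Least-squares exponential trend of a 2000-2010 series.

    lam is minus the OLS slope of log(value - floor) on year; series with
    fewer than two strictly positive observations after shifting off the
    floor yield a flat, flagged trend at the last usable level.
    """
    yr = np.asarray(list(years), dtype=float)
    val = np.asarray(list(values), dtype=float)
    if yr.size != val.size or yr.size < 2:
        raise ValueError("need at least two (year, value) observations")
    shifted = val - floor
    ok = shifted > 0
    if ok.sum() < 2:
        level = float(val[-1]) if np.isfinite(val[-1]) else floor
        return DecayTrend(level, 0.0, floor, cap, muni_id, name, degenerate=True)
    slope, intercept = np.polyfit(yr[ok], np.log(shifted[ok]), 1)
    level_2010 = floor + float(np.exp(intercept + slope * 2010.0))
    return DecayTrend(level_2010, -float(slope), floor, cap, muni_id, name)


def extrapolate(trend: DecayTrend, years: Iterable[int]) -> dict[int, float]:
    """Forecast values for the given years, clipped to [floor, cap]."""
    yr = np.asarray(list(years), dtype=float)
    vals = trend.floor + (trend.level_2010 - trend.floor) * np.exp(
        -trend.lam * (yr - 2010.0)
    )
    hi = trend.cap if trend.cap is not None else np.inf
    vals = np.clip(vals, trend.floor, hi)
    return {int(y): float(v) for y, v in zip(yr, vals)}


def calibrate_national(
    panel: MunicipalPanel,
    path: NationalCalibrationPath,
    interpolate: bool = True,
) -> MunicipalPanel:
    """Rescale a covariate so its national weighted mean hits path targets.

    Each municipality's value is multiplied by target / current national
    population-weighted mean for that year, then clipped to [0, 1]
    (proportional allocation of the national shock).  Because clipping
    pulls the mean back below the target, the rescale is iterated to its
    fixed point, which also makes the operation idempotent.
    """
    name = path.name
    if name not in panel.data.columns:
        raise KeyError(f"panel has no covariate {name!r}")
    targets = (
        path.interpolated(panel.years) if interpolate else dict(path.targets)
    )
    missing = [y for y in (path.targets if not interpolate else ()) if y not in set(panel.years)]
    if missing:
        raise ValueError(f"calibration target years absent from panel: {missing}")
    df = panel.data.copy()
    for year, target in targets.items():
        mask = df["year"] == year
        if not mask.any():
            raise ValueError(f"calibration target year {year} absent from panel")
        w = df.loc[mask, "population"].to_numpy(dtype=float)
        v = df.loc[mask, name].to_numpy(dtype=float)
        for _ in range(50):
            current = float(np.average(v, weights=w))
            if current <= 0 or abs(current - target) < 1e-13:
                break
            v = np.clip(v * (target / current), 0.0, 1.0)
            if (v >= 1.0).all():  # target unreachable, everyone at the cap
                break
        df.loc[mask, name] = v
    return MunicipalPanel(df, panel.covariates, truth=panel.truth, validate=False)


# ---------------------------------------------------------------------------
# panel-level forecasting
# ---------------------------------------------------------------------------

_TREND_WINDOW = (2000, 2010)
_SOCIOECONOMIC = (
    "poverty_rate",
    "log_illiteracy",
    "urbanisation",
    "public_beds",
    "private_beds",
    "log_private_insurance",
    "log_gdp_pc",
)


def forecast_panel(
    panel: MunicipalPanel,
    horizon: int = 2030,
    poverty_path: NationalCalibrationPath | None = None,
    trend_window: tuple[int, int] = _TREND_WINDOW,
) -> MunicipalPanel:
    """Extend the observed panel to ``horizon`` with extrapolated covariates.

    Socioeconomic covariates are replaced from 2011 onwards by their
    fitted-trend extrapolation (log-scale covariates are exponentiated
    back to the natural scale for fitting).  BFP coverage stays observed
    through the last panel year and is trend-extrapolated beyond it;
    population, race mix and doctor counts are carried forward at their
    last observed values; ESF coverage beyond the observed years is left
    undefined for the scenario engine to fill.
    """
    last_obs = int(panel.years.max())
    lo, hi = trend_window
    future_years = list(range(last_obs + 1, horizon + 1))
    extrap_years = list(range(hi + 1, horizon + 1))

    df = panel.data.copy()
    if future_years:
        last = df[df["year"] == last_obs].copy()
        blocks = []
        for year in future_years:
            block = last.copy()
            block["year"] = year
            block["esf_coverage"] = np.nan
            blocks.append(block)
        df = pd.concat([df] + blocks, ignore_index=True)

    # BFP is observed through last_obs (policy data), so only its future
    # years are extrapolated; the socioeconomic covariates are replaced
    # from the end of the trend window onwards (no municipal data there).
    targets = {name: extrap_years for name in _SOCIOECONOMIC if name in df.columns}
    if "bfp_coverage" in df.columns:
        targets["bfp_coverage"] = future_years
    years_fit = np.arange(lo, hi + 1)
    for name, years_out in targets.items():
        if not years_out:
            continue
        wide = panel.pivot(name, list(range(lo, hi + 1)))
        meta = COVARIATE_META[name]
        is_log = meta["kind"] == "log"
        cap = meta["cap"]
        series = np.exp(wide.values) if is_log else wide.values
        new_cols = {}
        for i, muni in enumerate(wide.index):
            trend = fit_decay_trend(
                years_fit, series[i], floor=0.0, cap=cap, muni_id=muni, name=name
            )
            new_cols[muni] = extrapolate(trend, years_out)
        proj = pd.DataFrame(new_cols).T.reindex(wide.index)
        if is_log:
            proj = np.log(proj.clip(lower=1e-12))
        tidy = proj.reset_index(names="muni_id").melt(
            id_vars="muni_id", var_name="year", value_name="_new"
        )
        df = df.merge(tidy, on=["muni_id", "year"], how="left")
        df[name] = df["_new"].fillna(df[name])
        df = df.drop(columns="_new")

    out = MunicipalPanel(df, panel.covariates, truth=panel.truth, validate=False)
    if poverty_path is not None:
        cal_years = [y for y in out.years if y in poverty_path.interpolated(out.years)]
        sub_path = NationalCalibrationPath(
            poverty_path.name, poverty_path.interpolated(cal_years)
        )
        out = calibrate_national(out, sub_path)
    return out
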