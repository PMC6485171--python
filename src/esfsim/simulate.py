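"""Monte Carlo engine over parameter and baseline uncertainty.

Each draw (i) samples every rate ratio from the normal distribution on
the log scale whose variance is calibrated to its 95% confidence
interval, (ii) resamples the observed baseline death counts from a
Poisson distribution and re-anchors the municipality fixed effects, and
(iii) propagates the deterministic model along every scenario coverage
trajectory.  Draw-level aggregates (unweighted and population-weighted
mean municipal rates, total expected deaths, poverty-quintile means and
the concentration index) are stored for every scenario, year and outcome
stratum; summaries report means and the 2.5%/97.5% quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .effects import EffectSizeTable, RateRatio
from .inequality import quintile_stratify
from .model import (
    BASE_YEAR,
    coverage_duration,
    _coverage_matrix,
    _require_coverage,
    _stack_covariates,
)
from .panel import MunicipalPanel

__all__ = [
    "DrawSpec",
    "SimulationResult",
    "draw_effects",
    "run_simulation",
    "summarize",
    "scenario_ratio",
    "excess_deaths",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class DrawSpec:
    """What the Monte Carlo varies and how many draws to take."""

    n_draws: int = 500
    master_seed: int = 0
    sample_effects: bool = True
    sample_baseline: bool = True
    rr_scale: str = "log"  # or "natural"
    keep_rates: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        if self.rr_scale not in ("log", "natural"):
            raise ValueError(f"unknown rr_scale {self.rr_scale!r}")


def _sample_rr(rr: RateRatio, rng: np.random.Generator, scale: str) -> RateRatio:
    if rr.lo == rr.hi:
        return rr
    if scale == "log":
        point = float(np.exp(np.log(rr.point) + rr.sigma * rng.standard_normal()))
    else:
        sd = (rr.hi - rr.lo) / (2.0 * _Z95)
        point = float(max(rr.point + sd * rng.standard_normal(), 1e-12))
    return RateRatio(point, min(rr.lo, point), max(rr.hi, point))


def draw_effects(
    table: EffectSizeTable, rng: np.random.Generator, scale: str = "log"
) -> EffectSizeTable:
    """One Monte Carlo realisation of the effect-size table.

    ln(RR) is drawn from Normal(ln point, sigma) with
    sigma = (ln hi - ln lo) / (2 * 1.96); a degenerate interval
    (lo == hi) leaves the value fixed.  ``scale="natural"`` samples the
    RR itself instead, truncated at zero.
    """
    new_strata = {}
    for name, se in table.strata.items():
        new_strata[name] = replace(
            se,
            rr_full=_sample_rr(se.rr_full, rng, scale),
            covariates={
                k: _sample_rr(v, rng, scale) for k, v in se.covariates.items()
            },
        )
    return replace(table, strata=new_strata)


# ---------------------------------------------------------------------------
# result container
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Draw-level aggregates of the Monte Carlo run.

    Arrays are indexed (draw, scenario, year, stratum); quintile means
    carry a trailing quintile axis.  ``rates`` (draw, scenario, year,
    municipality, stratum) is only present when requested.
    """

    scenarios: tuple
    years: np.ndarray
    strata: tuple
    muni_ids: np.ndarray
    n_draws: int
    seed: int
    mean_rates: np.ndarray
    wmean_rates: np.ndarray
    deaths_total: np.ndarray
    quintile_mean_rates: np.ndarray | None = None
    conc_index: np.ndarray | None = None
    rates: np.ndarray | None = None

    def _idx(self, scenario: str, year: int, stratum: str) -> tuple[int, int, int]:
        try:
            si = self.scenarios.index(scenario)
        except ValueError:
            raise KeyError(f"scenario {scenario!r} not simulated") from None
        yi = int(np.searchsorted(self.years, year))
        if yi >= self.years.size or self.years[yi] != year:
            raise KeyError(f"year {year} not simulated")
        try:
            ti = self.strata.index(stratum)
        except ValueError:
            raise KeyError(f"stratum {stratum!r} not simulated") from None
        return si, yi, ti

    def mean_rate_draws(self, scenario, year, stratum, weighted=False) -> np.ndarray:
        si, yi, ti = self._idx(scenario, year, stratum)
        arr = self.wmean_rates if weighted else self.mean_rates
        return arr[:, si, yi, ti]

    def deaths_draws(self, scenario, year, stratum) -> np.ndarray:
        si, yi, ti = self._idx(scenario, year, stratum)
        return self.deaths_total[:, si, yi, ti]

    def quintile_rates(self, scenario, year, stratum) -> np.ndarray:
        if self.quintile_mean_rates is None:
            raise ValueError("simulation was run without quintile stratification")
        si, yi, ti = self._idx(scenario, year, stratum)
        return self.quintile_mean_rates[:, si, yi, ti, :]

    def conc_index_draws(self, scenario, year, stratum) -> np.ndarray:
        if self.conc_index is None:
            raise ValueError("simulation was run without a poverty ranking")
        si, yi, ti = self._idx(scenario, year, stratum)
        return self.conc_index[:, si, yi, ti]


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


def _weighted_conc_index_matrix(
    rates: np.ndarray, ranks: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Concentration index per column of a (n_munis, T) rate matrix."""
    w = weights / weights.sum()
    mu = w @ rates  # (T,)
    rbar = float(w @ ranks)
    cov = ((ranks - rbar) * w) @ rates  # E[w (R-Rbar) y] = cov since E[w(R-Rbar)]mu = 0
    return 2.0 * cov / mu


def run_simulation(
    panel: MunicipalPanel,
    trajectories: Mapping[str, pd.DataFrame],
    effects: EffectSizeTable,
    spec: DrawSpec,
    strata: Iterable[str] = ("acsc_total",),
    anchor_years: tuple[int, int] = (2010, 2016),
    years: tuple[int, int] = (2010, 2030),
    parameterization: str = "continuous",
    poverty_baseline_year: int = 2010,
    quintile=None,
) -> SimulationResult:
    """Run the Monte Carlo over all scenarios, years and outcome strata.

    ``panel`` must carry covariates for the whole prediction window and
    observed deaths over the anchor window; ``trajectories`` maps scenario
    names to tidy coverage frames for the projection years.
    """
    strata = tuple(strata)
    scenario_names = tuple(trajectories)
    lo, hi = years
    year_list = [int(y) for y in panel.years if lo <= y <= hi]
    yr_arr = np.array(year_list, dtype=float)
    T = len(year_list)
    lag = effects.duration_lag_years

    sub = panel.subset_years(lo, hi)
    X, index = _stack_covariates(sub, year_list)
    n = index.size

    # person-years per stratum (n, T)
    py = {}
    for s in strata:
        pyw = (
            pd.DataFrame(
                {
                    "muni_id": sub.data["muni_id"],
                    "year": sub.data["year"],
                    "v": sub.person_years(s),
                }
            )
            .pivot(index="muni_id", columns="year", values="v")
            .reindex(index=index, columns=year_list)
            .values
        )
        py[s] = pyw

    # anchor-window data
    alo, ahi = anchor_years
    a_years = [int(y) for y in panel.years if alo <= y <= ahi]
    if not a_years:
        raise ValueError(f"panel has no years in anchor window {anchor_years}")
    a_sel = [year_list.index(y) for y in a_years if y in year_list]
    if len(a_sel) != len(a_years):
        raise ValueError("anchor window must lie inside the prediction window")
    a_yr = np.array(a_years, dtype=float)
    asub = panel.subset_years(alo, ahi)
    X_a = X[:, a_sel, :]
    obs_deaths = {}
    py_a = {}
    for s in strata:
        dw = (
            pd.DataFrame(
                {
                    "muni_id": asub.data["muni_id"],
                    "year": asub.data["year"],
                    "v": asub.deaths(s).astype(float),
                }
            )
            .pivot(index="muni_id", columns="year", values="v")
            .reindex(index=index, columns=a_years)
            .values
        )
        obs_deaths[s] = dw
        py_a[s] = py[s][:, a_sel]

    # scenario coverage, duration and unit coverage-effect matrices
    pq = quintile
    if pq is None and "poverty_rate" in panel.data.columns:
        try:
            pq = quintile_stratify(panel, poverty_baseline_year).reindex(index).values
        except (ValueError, KeyError):
            pq = None
    mult = np.ones(n)
    if pq is not None and tuple(effects.poverty_multipliers) != (1.0,) * 5:
        mult = np.asarray(effects.poverty_multipliers)[np.asarray(pq) - 1]

    ceff_unit = {}  # scenario -> (n, T); multiply by ln(rr_full) per draw
    for name, traj in trajectories.items():
        covw = _coverage_matrix(panel, traj)
        _require_coverage(covw, year_list)
        dur = coverage_duration(np.nan_to_num(covw.values, nan=0.0))
        sel = [list(covw.columns).index(y) for y in year_list]
        cov_m = covw.values[:, sel]
        ramp = np.minimum(dur[:, sel] / float(lag), 1.0)
        if parameterization == "continuous":
            unit = cov_m * ramp
        elif parameterization == "categorical":
            consolidated = (cov_m >= 0.7) & (ramp >= 1.0)
            consolidating = (cov_m >= 0.7) & ~consolidated
            unit = consolidated * 1.0 + consolidating * 0.5
        else:
            raise ValueError(f"unknown parameterization {parameterization!r}")
        ceff_unit[name] = unit * mult[:, None]

    # inequality precomputations
    pop = (
        panel.data.drop_duplicates("muni_id")
        .set_index("muni_id")["population"]
        .reindex(index)
        .to_numpy(dtype=float)
    )
    have_poverty = "poverty_rate" in panel.data.columns
    ranks = None
    if have_poverty:
        try:
            povb = panel.baseline_covariate("poverty_rate", poverty_baseline_year)
            povb = povb.reindex(index).to_numpy(dtype=float)
            order = np.argsort(-povb, kind="stable")
            wo = pop[order] / pop.sum()
            rr = np.cumsum(wo) - 0.5 * wo
            ranks = np.empty(n)
            ranks[order] = rr
        except ValueError:
            ranks = None

    S, K = len(scenario_names), len(strata)
    D = spec.n_draws
    mean_rates = np.empty((D, S, T, K))
    wmean_rates = np.empty((D, S, T, K))
    deaths_total = np.empty((D, S, T, K))
    quint = np.empty((D, S, T, K, 5)) if pq is not None else None
    conc = np.empty((D, S, T, K)) if ranks is not None else None
    full = np.empty((D, S, T, n, K)) if spec.keep_rates else None

    qmasks = None
    if pq is not None:
        qmasks = [np.asarray(pq) == q for q in range(1, 6)]
        if any(not m.any() for m in qmasks):  # too few municipalities
            qmasks = None
            quint = None

    wpop = pop / pop.sum()
    ss = np.random.SeedSequence(spec.master_seed)
    child_seeds = ss.spawn(D)
    names = list(effects.strata)

    for d in range(D):
        rng = np.random.default_rng(child_seeds[d])
        table_d = (
            draw_effects(effects, rng, spec.rr_scale)
            if spec.sample_effects
            else effects
        )
        for ti, s in enumerate(strata):
            se = table_d[s]
            lnbeta = np.array(se.covariate_lnrr(panel.covariates))
            lnrr = se.rr_full.ln
            deaths_d = (
                rng.poisson(obs_deaths[s]).astype(float)
                if spec.sample_baseline
                else obs_deaths[s]
            )
            eta_a = X_a @ lnbeta + se.gamma * (a_yr - BASE_YEAR)[None, :]
            corrected = np.where(deaths_d == 0, 0.5, deaths_d)
            log_obs = np.log(corrected / py_a[s] * 1e5)
            eta_full = X @ lnbeta + se.gamma * (yr_arr - BASE_YEAR)[None, :]
            for si, name in enumerate(scenario_names):
                ceff = ceff_unit[name] * lnrr
                alpha = (log_obs - eta_a - ceff[:, a_sel]).mean(axis=1)
                rates = np.exp(alpha[:, None] + eta_full + ceff)
                mean_rates[d, si, :, ti] = rates.mean(axis=0)
                wmean_rates[d, si, :, ti] = wpop @ rates
                deaths_total[d, si, :, ti] = (rates * py[s] / 1e5).sum(axis=0)
                if quint is not None:
                    for q in range(5):
                        quint[d, si, :, ti, q] = rates[qmasks[q]].mean(axis=0)
                if conc is not None:
                    conc[d, si, :, ti] = _weighted_conc_index_matrix(
                        rates, ranks, pop
                    )
                if full is not None:
                    full[d, si, :, :, ti] = rates.T

    return SimulationResult(
        scenarios=scenario_names,
        years=np.array(year_list),
        strata=strata,
        muni_ids=index.to_numpy(),
        n_draws=D,
        seed=spec.master_seed,
        mean_rates=mean_rates,
        wmean_rates=wmean_rates,
        deaths_total=deaths_total,
        quintile_mean_rates=quint,
        conc_index=conc,
        rates=full,
    )


# ---------------------------------------------------------------------------
# summaries and comparisons
# ---------------------------------------------------------------------------


def summarize(
    result: SimulationResult,
    weighted: bool = False,
    levels: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Mean municipal rate with credible interval per scenario/year/stratum."""
    arr = result.wmean_rates if weighted else result.mean_rates
    rows = []
    for si, scen in enumerate(result.scenarios):
        for yi, year in enumerate(result.years):
            for ti, s in enumerate(result.strata):
                draws = arr[:, si, yi, ti]
                rows.append(
                    {
                        "scenario": scen,
                        "year": int(year),
                        "stratum": s,
                        "mean": float(draws.mean()),
                        "ci_lo": float(np.quantile(draws, levels[0])),
                        "ci_hi": float(np.quantile(draws, levels[1])),
                    }
                )
    return pd.DataFrame(rows)


def scenario_ratio(
    result: SimulationResult,
    a: str,
    b: str,
    year: int,
    stratum: str = "acsc_total",
    levels: tuple[float, float] = (0.025, 0.975),
) -> dict[str, float]:
    """Per-draw ratio of mean municipal rates a/b, with credible interval."""
    ra = result.mean_rate_draws(a, year, stratum)
    rb = result.mean_rate_draws(b, year, stratum)
    ok = rb > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} draws with zero denominator rate",
            RuntimeWarning,
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("denominator rate is zero in every draw")
    ratio = ra[ok] / rb[ok]
    return {
        "ratio": float(ratio.mean()),
        "ci_lo": float(np.quantile(ratio, levels[0])),
        "ci_hi": float(np.quantile(ratio, levels[1])),
    }


def excess_deaths(
    result: SimulationResult,
    a: str,
    b: str,
    years: Iterable[int] | None = None,
    stratum: str = "acsc_total",
    levels: tuple[float, float] = (0.025, 0.975),
) -> dict[str, float]:
    """Excess deaths under scenario a versus b summed over years.

    Per draw: sum over municipalities and years of
    (rate_a - rate_b) * person_years / 1e5; antisymmetric in (a, b).
    Default years are the projection period 2017 onwards.
    """
    if years is None:
        years = [int(y) for y in result.years if y >= 2017]
    total = np.zeros(result.n_draws)
    for year in years:
        total += result.deaths_draws(a, year, stratum) - result.deaths_draws(
            b, year, stratum
        )
    return {
        "excess_deaths": float(total.mean()),
        "ci_lo": float(np.quantile(total, levels[0])),
        "ci_hi": float(np.quantile(total, levels[1])),
    }
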