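"""Synthetic municipal cohort generator.

Creates a panel of municipalities (2000-2016 by default) with the
statistical structure the downstream analysis assumes: covariate
cross-sections moment-matched to configurable targets at an anchor year,
exact per-municipality exponential histories with multiplicative
log-normal noise (so trend fitting has recoverable ground truth), a
logistic ESF coverage expansion, Mais Medicos doctors concentrated in
high-poverty municipalities from 2013, and Poisson death counts drawn
from the fixed-effects mortality model itself with known municipality
intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special

from .effects import (
    COVARIATE_META,
    COVARIATES,
    EffectSizeTable,
    default_effect_table,
)
from .model import (
    coverage_duration,
    coverage_effect,
    _coverage_matrix,
    _linear_predictor,
    _stack_covariates,
)
from .panel import MunicipalPanel

__all__ = [
    "CovariateSpec",
    "CohortParams",
    "generate_cohort",
    "assign_mmp_doctors",
    "generate_deaths",
    "generate_full_cohort",
]

_REGIONS = ("North", "Northeast", "Southeast", "South", "Centre-West")


@dataclass(frozen=True)
class CovariateSpec:
    """Generation targets for one covariate.

    ``mean``/``sd`` are the cross-sectional moments at ``anchor_year``;
    ``lam_mean``/``lam_sd`` the distribution of per-municipality
    exponential decay rates (positive = decline over time) applied to the
    covariate on its natural scale; ``noise_sd`` the per-year
    multiplicative log-normal noise.
    """

    mean: float
    sd: float
    kind: str  # "fraction" | "log" | "positive"
    lam_mean: float = 0.0
    lam_sd: float = 0.02
    anchor_year: int = 2015
    noise_sd: float = 0.05
    cap: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0 or self.noise_sd < 0 or self.lam_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.kind == "fraction" and not (0.0 <= self.mean <= 1.0):
            raise ValueError(
                f"mean {self.mean} impossible for a fraction covariate"
            )
        if self.kind == "positive" and self.mean < 0:
            raise ValueError("mean of a positive covariate must be >= 0")


def default_covariate_specs() -> dict[str, CovariateSpec]:
    """Anchor-year (2015) moments and decade trends for the model covariates."""
    return {
        "bfp_coverage": CovariateSpec(0.335, 0.221, "fraction", 0.0, 0.02, cap=1.0),
        "poverty_rate": CovariateSpec(0.138, 0.153, "fraction", 0.05, 0.02, cap=1.0),
        "log_illiteracy": CovariateSpec(-2.37, 0.79, "log", 0.05, 0.015, cap=1.0),
        "urbanisation": CovariateSpec(0.684, 0.222, "fraction", -0.005, 0.005, cap=1.0),
        "public_beds": CovariateSpec(0.13, 0.21, "positive", 0.0, 0.01),
        "private_beds": CovariateSpec(0.04, 0.10, "positive", 0.0, 0.01),
        "log_private_insurance": CovariateSpec(-5.62, 1.62, "log", -0.01, 0.01, cap=1.0),
        "log_gdp_pc": CovariateSpec(-4.70, 0.71, "log", -0.01, 0.01),
    }


@dataclass(frozen=True)
class CohortParams:
    n_municipalities: int = 500
    year_start: int = 2000
    year_end: int = 2016
    master_seed: int = 0
    covariates: Mapping[str, CovariateSpec] = field(
        default_factory=default_covariate_specs
    )
    # ESF coverage cross-section at the 2016 anchor plus logit-scale growth
    coverage_mean: float = 0.804
    coverage_sd: float = 0.235
    coverage_anchor_year: int = 2016
    coverage_growth_mean: float = 0.25  # logit units per year
    coverage_growth_sd: float = 0.08
    coverage_noise_sd: float = 0.05
    # Mais Medicos allocation
    mmp_start_year: int = 2013
    mmp_strength: float = 2.0  # exponential poverty-rank link
    mmp_scale: float = 0.25  # max mean coverage contribution (poorest)
    # population and race composition
    population_median: float = 12000.0
    population_sigma: float = 1.0
    race_mix_alpha: float = 4.0
    race_mix_beta: float = 4.0
    # mortality intercept dispersion
    alpha_sd: float = 0.3
    alpha_poverty_slope: float = 1.0
    true_effects: EffectSizeTable = field(default_factory=default_effect_table)

    def __post_init__(self) -> None:
        if self.n_municipalities < 2:
            raise ValueError("need at least 2 municipalities")
        if not (0.0 <= self.coverage_mean <= 1.0):
            raise ValueError("coverage mean must be a fraction")
        if min(self.coverage_sd, self.alpha_sd, self.population_sigma) < 0:
            raise ValueError("standard deviations must be non-negative")
        for name, spec in self.covariates.items():
            if name not in COVARIATE_META:
                raise ValueError(f"unknown covariate {name!r}")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)


# ---------------------------------------------------------------------------
# moment-matched anchor cross-sections
# ---------------------------------------------------------------------------

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


def _logit_normal_moments(mu: float, sigma: float) -> tuple[float, float]:
    vals = special.expit(mu + sigma * _GH_NODES)
    m1 = float(np.dot(_GH_WEIGHTS, vals))
    m2 = float(np.dot(_GH_WEIGHTS, vals**2))
    return m1, float(np.sqrt(max(m2 - m1 * m1, 0.0)))


def logit_normal_params(mean: float, sd: float) -> tuple[float, float]:
    """Logit-scale (mu, sigma) whose back-transform has the given moments."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"fraction mean must be strictly inside (0, 1), got {mean}")
    if sd == 0.0:
        return float(special.logit(mean)), 0.0
    max_sd = float(np.sqrt(mean * (1.0 - mean)))
    if sd >= max_sd:
        raise ValueError(
            f"sd {sd} unattainable for a [0,1] variable with mean {mean} "
            f"(upper bound {max_sd:.4f})"
        )

    def residual(p):
        m, s = _logit_normal_moments(p[0], abs(p[1]))
        return [m - mean, s - sd]

    x0 = [float(special.logit(mean)), sd / (mean * (1.0 - mean))]
    sol = optimize.least_squares(residual, x0, xtol=1e-14, ftol=1e-14)
    mu, sigma = float(sol.x[0]), abs(float(sol.x[1]))
    m, s = _logit_normal_moments(mu, sigma)
    if abs(m - mean) > 1e-6 or abs(s - sd) > 1e-5:
        raise ValueError(
            f"could not match logit-normal moments mean={mean}, sd={sd}"
        )
    return mu, sigma


def _anchor_draw(spec: CovariateSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Cross-section at the anchor year with the target mean and sd."""
    if spec.sd == 0.0:
        return np.full(n, spec.mean)
    if spec.kind == "fraction":
        mu, sigma = logit_normal_params(spec.mean, spec.sd)
        return special.expit(mu + sigma * rng.standard_normal(n))
    if spec.kind == "log":
        return spec.mean + spec.sd * rng.standard_normal(n)
    # positive: log-normal with exact mean/sd
    s2 = np.log1p((spec.sd / spec.mean) ** 2)
    mu = np.log(spec.mean) - 0.5 * s2
    return np.exp(mu + np.sqrt(s2) * rng.standard_normal(n))


def _history(
    anchor: np.ndarray,
    lam: np.ndarray,
    years: np.ndarray,
    anchor_year: int,
    noise_sd: float,
    rng: np.random.Generator,
    kind: str,
    cap: float | None,
) -> np.ndarray:
    """Exponential trajectories around the anchor cross-section.

    On the natural scale value(t) = anchor * exp(-lam * (t - anchor_year))
    with multiplicative log-normal noise; the anchor year itself is
    noise-free so cross-sectional moments are preserved there.  "log"
    covariates store the log, so the trend is linear there.
    """
    n = anchor.shape[0]
    offsets = -lam[:, None] * (years - anchor_year)[None, :]
    noise = noise_sd * rng.standard_normal((n, years.size))
    noise[:, years == anchor_year] = 0.0
    if kind == "log":
        vals = anchor[:, None] + offsets + noise
        if cap is not None:
            vals = np.minimum(vals, np.log(cap))
        return vals
    vals = anchor[:, None] * np.exp(offsets + noise)
    lo = 0.0
    hi = cap if cap is not None else np.inf
    return np.clip(vals, lo, hi)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def generate_cohort(params: CohortParams) -> MunicipalPanel:
    """Generate the covariate/coverage panel (no doctors, no deaths yet)."""
    n = params.n_municipalities
    years = np.array(list(params.years))
    ss = np.random.SeedSequence(params.master_seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    muni_ids = np.array([f"M{idx:05d}" for idx in range(1, n + 1)])
    region = rng.choice(_REGIONS, size=n, p=(0.10, 0.33, 0.30, 0.17, 0.10))
    population = np.maximum(
        np.round(
            params.population_median
            * np.exp(params.population_sigma * rng.standard_normal(n))
        ),
        200.0,
    )
    race_mix = rng.beta(params.race_mix_alpha, params.race_mix_beta, size=n)

    columns: dict[str, np.ndarray] = {}
    truth_lambdas: dict[str, np.ndarray] = {}
    for name in COVARIATES:
        if name not in params.covariates:
            raise ValueError(f"no generation spec for covariate {name!r}")
        spec = params.covariates[name]
        anchor = _anchor_draw(spec, n, rng)
        lam = spec.lam_mean + spec.lam_sd * rng.standard_normal(n)
        columns[name] = _history(
            anchor, lam, years, spec.anchor_year, spec.noise_sd, rng,
            spec.kind, spec.cap,
        )
        truth_lambdas[name] = lam

    # ESF coverage: logit-normal 2016 cross-section, logistic expansion back
    if params.coverage_sd > 0:
        mu, sigma = logit_normal_params(params.coverage_mean, params.coverage_sd)
        logit_anchor = mu + sigma * rng.standard_normal(n)
    else:
        logit_anchor = np.full(n, special.logit(params.coverage_mean))
    growth = np.maximum(
        params.coverage_growth_mean
        + params.coverage_growth_sd * rng.standard_normal(n),
        0.02,
    )
    lnoise = params.coverage_noise_sd * rng.standard_normal((n, years.size))
    lnoise[:, years == params.coverage_anchor_year] = 0.0
    logit_cov = (
        logit_anchor[:, None]
        - growth[:, None] * (params.coverage_anchor_year - years)[None, :]
        + lnoise
    )
    coverage = special.expit(logit_cov)

    rows = {
        "muni_id": np.repeat(muni_ids, years.size),
        "year": np.tile(years, n),
        "population": np.repeat(population, years.size),
        "region": np.repeat(region, years.size),
        "race_mix": np.repeat(race_mix, years.size),
        "esf_coverage": coverage.reshape(-1),
        "mmp_doctors": np.zeros(n * years.size, dtype=int),
    }
    for name in COVARIATES:
        rows[name] = columns[name].reshape(-1)
    df = pd.DataFrame(rows)
    truth = {
        "lambdas": truth_lambdas,
        "coverage_growth": growth,
        "params": params,
    }
    return MunicipalPanel(df, covariates=COVARIATES, truth=truth)


def assign_mmp_doctors(panel: MunicipalPanel, params: CohortParams) -> MunicipalPanel:
    """Allocate Mais Medicos doctors, concentrated in poor municipalities.

    Doctors appear from ``mmp_start_year`` onwards (zero before) at a
    constant per-municipality level drawn Poisson with mean
    ``scale * population/3450 * exp(strength * (poverty_rank - 1))`` where
    the fractional poverty rank is 1 for the poorest municipality.
    """
    if "poverty_rate" not in panel.data.columns:
        raise ValueError("panel must carry a poverty_rate covariate")
    rng = np.random.default_rng(np.random.SeedSequence(params.master_seed).spawn(2)[1])
    base_year = min(2010, panel.years.max())
    poverty = panel.baseline_covariate("poverty_rate", base_year)
    ids = poverty.index.to_numpy()
    rank = pd.Series(poverty.values, index=ids).rank(method="average").to_numpy()
    rank = rank / rank.size  # in (0, 1], 1 = poorest
    pop = (
        panel.data.drop_duplicates("muni_id").set_index("muni_id")["population"]
        .reindex(ids)
        .to_numpy()
    )
    mean_doctors = (
        params.mmp_scale * pop / 3450.0 * np.exp(params.mmp_strength * (rank - 1.0))
    )
    doctors = rng.poisson(mean_doctors)
    lookup = pd.Series(doctors, index=ids)
    df = panel.data.copy()
    df["mmp_doctors"] = np.where(
        df["year"] >= params.mmp_start_year,
        lookup.reindex(df["muni_id"]).to_numpy(),
        0,
    ).astype(int)
    return MunicipalPanel(df, panel.covariates, truth=panel.truth, validate=False)


def _expected_rates(
    panel: MunicipalPanel,
    effects: EffectSizeTable,
    stratum: str,
    alphas: pd.Series,
    parameterization: str = "continuous",
) -> pd.DataFrame:
    """Wide (muni x year) expected rates with observed coverage."""
    years = list(panel.years)
    covw = _coverage_matrix(panel, None)
    dur = coverage_duration(covw.values)
    X, index = _stack_covariates(panel, years)
    se = effects[stratum]
    eta = _linear_predictor(X, np.array(years), se, panel.covariates)
    ceff = coverage_effect(covw.values, dur, effects, stratum, parameterization)
    rates = np.exp(alphas.reindex(index).values[:, None] + eta + ceff)
    return pd.DataFrame(rates, index=index, columns=years)


def _draw_alphas(
    panel: MunicipalPanel,
    effects: EffectSizeTable,
    params: CohortParams,
    rng: np.random.Generator,
) -> dict[str, pd.Series]:
    """True municipality intercepts, centred so 2010 mean rates hit targets."""
    base_year = min(2010, params.year_end)
    poverty = panel.baseline_covariate("poverty_rate", base_year)
    index = poverty.index
    pov_dev = poverty.values - poverty.values.mean()
    alphas = {}
    for stratum, se in effects.strata.items():
        raw = params.alpha_poverty_slope * pov_dev + params.alpha_sd * rng.standard_normal(
            index.size
        )
        prelim = pd.Series(raw, index=index)
        rates = _expected_rates(panel, effects, stratum, prelim)
        shift = np.log(se.baseline_rate) - np.log(rates[base_year].mean())
        alphas[stratum] = prelim + shift
    return alphas


def generate_deaths(
    panel: MunicipalPanel,
    effects: EffectSizeTable | None = None,
    seed: int | None = None,
    alphas: Mapping[str, pd.Series] | None = None,
    distribution: str = "poisson",
    params: CohortParams | None = None,
) -> MunicipalPanel:
    """Draw death counts per outcome stratum from the mortality model.

    deaths ~ Poisson(rate * person_years / 1e5) independently per stratum
    (``distribution="expected"`` stores the noise-free expectations, useful
    for exact-recovery checks).  True intercepts are drawn here unless
    supplied, and are stored in ``panel.truth["alphas"]``.
    """
    if distribution not in ("poisson", "expected"):
        raise ValueError(f"unknown distribution {distribution!r}")
    params = params or panel.truth.get("params")
    if params is None:
        raise ValueError("need CohortParams (pass params= or use a generated panel)")
    effects = effects if effects is not None else params.true_effects
    rng = np.random.default_rng(
        np.random.SeedSequence(
            params.master_seed if seed is None else seed
        ).spawn(3)[2]
    )
    if alphas is None:
        alphas = _draw_alphas(panel, effects, params, rng)

    df = panel.data.copy()
    stale = [c for c in df.columns if c.startswith("deaths_")]
    df = df.drop(columns=stale)
    years = list(panel.years)
    for stratum in effects.strata:
        rates = _expected_rates(panel, effects, stratum, alphas[stratum])
        if (rates.values < 0).any():
            raise RuntimeError(f"negative expected rate in stratum {stratum}")
        py = (
            pd.DataFrame(
                {
                    "muni_id": df["muni_id"],
                    "year": df["year"],
                    "v": panel.person_years(stratum),
                }
            )
            .pivot(index="muni_id", columns="year", values="v")
            .reindex(index=rates.index, columns=years)
        )
        mu = rates.values * py.values / 1e5
        deaths = mu if distribution == "expected" else rng.poisson(mu).astype(float)
        deaths = np.minimum(deaths, py.values)  # cannot exceed people at risk
        tidy = (
            pd.DataFrame(deaths, index=rates.index, columns=years)
            .reset_index()
            .melt(id_vars="muni_id", var_name="year", value_name=f"deaths_{stratum}")
        )
        df = df.merge(tidy, on=["muni_id", "year"], how="left")
    truth = dict(panel.truth)
    truth["alphas"] = dict(alphas)
    return MunicipalPanel(df, panel.covariates, truth=truth, validate=False)


def generate_full_cohort(params: CohortParams) -> MunicipalPanel:
    """Covariates + coverage + doctors + deaths in one deterministic call."""
    panel = generate_cohort(params)
    panel = assign_mmp_doctors(panel, params)
    return generate_deaths(panel, params.true_effects, params=params)
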