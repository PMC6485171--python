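"""Effect-size tables for the ACSC mortality model.

The mortality model is log-linear in a set of municipal covariates plus a
primary-care (ESF) coverage term.  All effects are expressed as rate ratios
(RR) with 95% confidence intervals; the Monte Carlo engine samples them on
the log scale with the variance implied by the interval.  The full-coverage
rate ratio ``rr_full`` is the multiplicative change in the mortality rate
when a municipality moves from no ESF coverage to sustained (past the
duration lag) 100% coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "RateRatio",
    "StratumEffects",
    "EffectSizeTable",
    "COVARIATES",
    "COVARIATE_META",
    "CAUSE_STRATA",
    "RACE_STRATA",
    "ALL_STRATA",
    "default_effect_table",
]

#: model covariates, on the scales they enter the linear predictor
#: (fractions for coverage/rates, natural logs where the name says log).
COVARIATES = (
    "bfp_coverage",
    "poverty_rate",
    "log_illiteracy",
    "urbanisation",
    "public_beds",
    "private_beds",
    "log_private_insurance",
    "log_gdp_pc",
)

#: covariate kind for generation/forecasting: "fraction" lives in [0,1],
#: "log" is the natural log of a positive quantity (cap applies to the
#: underlying quantity), "positive" is unbounded above but >= 0.
COVARIATE_META: Mapping[str, dict] = {
    "bfp_coverage": {"kind": "fraction", "cap": 1.0},
    "poverty_rate": {"kind": "fraction", "cap": 1.0},
    "log_illiteracy": {"kind": "log", "cap": 1.0},
    "urbanisation": {"kind": "fraction", "cap": 1.0},
    "public_beds": {"kind": "positive", "cap": None},
    "private_beds": {"kind": "positive", "cap": None},
    "log_private_insurance": {"kind": "log", "cap": 1.0},
    "log_gdp_pc": {"kind": "log", "cap": None},
}

CAUSE_STRATA = ("acsc_total", "nutritional", "infectious", "cardiovascular")
RACE_STRATA = ("acsc_black", "acsc_white")
ALL_STRATA = CAUSE_STRATA + RACE_STRATA


@dataclass(frozen=True)
class RateRatio:
    """A rate ratio with its 95% confidence interval.

    ``sigma`` is the standard deviation of ln(RR) implied by treating the
    interval as a symmetric normal interval on the log scale:
    sigma = (ln hi - ln lo) / (2 * 1.96).
    """

    point: float
    lo: float | None = None
    hi: float | None = None

    def __post_init__(self) -> None:
        if self.point <= 0:
            raise ValueError(f"rate ratio must be positive, got {self.point}")
        lo = self.point if self.lo is None else self.lo
        hi = self.point if self.hi is None else self.hi
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)
        if not (0 < self.lo <= self.point <= self.hi):
            raise ValueError(
                f"confidence interval ({self.lo}, {self.hi}) must bracket "
                f"the point estimate {self.point}"
            )

    @property
    def ln(self) -> float:
        return math.log(self.point)

    @property
    def sigma(self) -> float:
        return (math.log(self.hi) - math.log(self.lo)) / (2.0 * 1.959963984540054)


@dataclass(frozen=True)
class StratumEffects:
    """Effects for one outcome stratum (a cause group or race stratum)."""

    rr_full: RateRatio
    covariates: Mapping[str, RateRatio]
    gamma: float = -0.022  # secular trend: per-year change in log rate
    baseline_rate: float = 100.0  # generator target mean rate per 100k in 2010

    def covariate_lnrr(self, names) -> list[float]:
        out = []
        for name in names:
            if name not in self.covariates:
                raise KeyError(f"no effect configured for covariate {name!r}")
            out.append(self.covariates[name].ln)
        return out


@dataclass(frozen=True)
class EffectSizeTable:
    """Per-stratum effect sizes plus shared structural parameters.

    ``duration_lag_years`` is the number of years of sustained coverage
    before the full ESF effect applies; ``poverty_multipliers`` scale
    ln(rr_full) per baseline-poverty quintile (1 = poorest) and default to
    no stratification.
    """

    strata: Mapping[str, StratumEffects]
    duration_lag_years: int = 4
    poverty_multipliers: tuple = (1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.duration_lag_years < 1:
            raise ValueError("duration_lag_years must be >= 1")
        if len(self.poverty_multipliers) != 5:
            raise ValueError("poverty_multipliers needs one entry per quintile")

    def __getitem__(self, stratum: str) -> StratumEffects:
        try:
            return self.strata[stratum]
        except KeyError:
            raise KeyError(
                f"unknown outcome stratum {stratum!r}; have {sorted(self.strata)}"
            ) from None

    def with_gamma_shift(self, delta: float) -> "EffectSizeTable":
        """Shift every stratum's secular trend by ``delta`` (per year)."""
        new = {
            s: replace(se, gamma=se.gamma + delta) for s, se in self.strata.items()
        }
        return replace(self, strata=new)


def _shared_covariate_effects() -> dict[str, RateRatio]:
    # Default per-unit covariate rate ratios on the covariate-table scales
    # (fractions, logs).  Package defaults, ordinarily replaced by the
    # coefficients of a fitted impact-evaluation model via config; see
    # docs/methods.md.
    return {
        "bfp_coverage": RateRatio(0.92, 0.88, 0.96),
        "poverty_rate": RateRatio(1.80, 1.50, 2.16),
        "log_illiteracy": RateRatio(1.06, 1.02, 1.10),
        "urbanisation": RateRatio(0.95, 0.90, 1.00),
        "public_beds": RateRatio(0.97, 0.94, 1.00),
        "private_beds": RateRatio(0.98, 0.95, 1.01),
        "log_private_insurance": RateRatio(0.97, 0.94, 1.00),
        "log_gdp_pc": RateRatio(0.94, 0.90, 0.98),
    }


def default_effect_table() -> EffectSizeTable:
    """Default effect-size table.

    The cause-specific full-coverage rate ratios encode mortality
    reductions of 52% (nutritional deficiencies and anaemia), 21%
    (infectious diseases) and 15% (cardiovascular disease) at sustained
    full municipal ESF coverage.  The overall-ACSC and race-stratum values
    are package defaults (see docs/methods.md) and are ordinary config
    inputs.
    """
    cov = _shared_covariate_effects()
    strata = {
        "acsc_total": StratumEffects(
            rr_full=RateRatio(0.85, 0.80, 0.90), covariates=cov, baseline_rate=100.0
        ),
        "nutritional": StratumEffects(
            rr_full=RateRatio(0.48, 0.40, 0.58), covariates=cov, baseline_rate=5.0
        ),
        "infectious": StratumEffects(
            rr_full=RateRatio(0.79, 0.72, 0.86), covariates=cov, baseline_rate=20.0
        ),
        "cardiovascular": StratumEffects(
            rr_full=RateRatio(0.85, 0.79, 0.91), covariates=cov, baseline_rate=55.0
        ),
        "acsc_black": StratumEffects(
            rr_full=RateRatio(0.80, 0.74, 0.87), covariates=cov, baseline_rate=120.0
        ),
        "acsc_white": StratumEffects(
            rr_full=RateRatio(0.89, 0.84, 0.94), covariates=cov, baseline_rate=85.0
        ),
    }
    return EffectSizeTable(strata=strata)
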