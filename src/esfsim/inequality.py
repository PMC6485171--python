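"""Between- and within-municipality inequality metrics.

Covers the three inequality summaries of the analysis: the concentration
index of municipal mortality rates along the poverty gradient, poverty-
quintile rate differences between scenarios, and the standardised rate
ratio (SRR) of black/pardo to white ACSC mortality.
"""

from __future__ import annotations

import warnings
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .panel import MunicipalPanel

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import SimulationResult

__all__ = [
    "quintile_stratify",
    "concentration_index",
    "quintile_rate_difference",
    "standardised_rate_ratio",
]


def quintile_stratify(panel: MunicipalPanel, baseline_year: int = 2010) -> pd.Series:
    """Poverty quintiles of municipalities at the baseline year.

    Quintile 1 is the poorest fifth.  The assignment is frozen at the
    baseline year (later poverty changes do not move municipalities) and
    ties are broken by stable municipality-id order.  Quintile sizes
    differ by at most one.
    """
    poverty = panel.baseline_covariate("poverty_rate", baseline_year)
    poverty = poverty.sort_index(kind="stable")
    # poorest first; mergesort keeps id order within ties
    order = np.argsort(-poverty.to_numpy(), kind="stable")
    n = poverty.size
    quintile = np.empty(n, dtype=int)
    quintile[order] = np.arange(n) * 5 // n + 1
    return pd.Series(quintile, index=poverty.index, name="poverty_quintile")


def concentration_index(rates, rank_var, weights=None) -> float:
    """Concentration index C = 2 cov_w(y, R) / mu.

    ``rank_var`` orders municipalities from poorest (largest value, e.g. a
    poverty rate) to richest; R is the weighted fractional rank running
    from 0 at the poorest to 1 at the richest.  C > 0 means mortality is
    concentrated among richer municipalities, C < 0 among poorer ones.
    """
    y = np.asarray(rates, dtype=float)
    v = np.asarray(rank_var, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two municipalities")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive total")
    mu = float(np.average(y, weights=w))
    if mu <= 0:
        raise ValueError("mean rate must be strictly positive")
    order = np.argsort(-v, kind="stable")  # poorest first, ties by input order
    wo = w[order]
    frac = wo / wo.sum()
    ranks = np.cumsum(frac) - 0.5 * frac
    r = np.empty_like(ranks)
    r[order] = ranks
    cov = float(np.average((y - mu) * (r - np.average(r, weights=w)), weights=w))
    return 2.0 * cov / mu


def quintile_rate_difference(
    result: "SimulationResult",
    a: str,
    b: str,
    year: int,
    stratum: str = "acsc_total",
    levels: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Per-quintile mean-rate differences (scenario a minus b) with CIs.

    Computed per Monte Carlo draw from quintile-level mean municipal
    rates, then summarised as mean and the 2.5%/97.5% quantiles.
    """
    qa = result.quintile_rates(a, year, stratum)  # (draws, 5)
    qb = result.quintile_rates(b, year, stratum)
    diff = qa - qb
    rows = []
    for q in range(5):
        d = diff[:, q]
        rows.append(
            {
                "quintile": q + 1,
                "rd": float(d.mean()),
                "ci_lo": float(np.quantile(d, levels[0])),
                "ci_hi": float(np.quantile(d, levels[1])),
            }
        )
    out = pd.DataFrame(rows)
    out.insert(0, "scenario_pair", f"{a} - {b}")
    return out


def standardised_rate_ratio(
    result: "SimulationResult",
    scenario: str,
    year: int,
    black_stratum: str = "acsc_black",
    white_stratum: str = "acsc_white",
    levels: tuple[float, float] = (0.025, 0.975),
) -> dict[str, float]:
    """SRR: mean municipal black/pardo rate over white rate, per draw.

    Draws with a zero white rate are excluded with a warning.  Returns the
    mean and credible interval over draws.
    """
    black = result.mean_rate_draws(scenario, year, black_stratum)
    white = result.mean_rate_draws(scenario, year, white_stratum)
    ok = white > 0
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} draws with zero white-stratum rate",
            RuntimeWarning,
            stacklevel=2,
        )
    if not ok.any():
        raise ValueError("white-stratum rate is zero in every draw")
    srr = black[ok] / white[ok]
    return {
        "srr": float(srr.mean()),
        "ci_lo": float(np.quantile(srr, levels[0])),
        "ci_hi": float(np.quantile(srr, levels[1])),
    }
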