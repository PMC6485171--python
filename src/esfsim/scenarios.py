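"""Policy scenarios for ESF coverage trajectories 2017-2030.

Four scenarios map each municipality's observed 2016 coverage (and its
Mais Medicos contribution) onto a coverage path:

* ``status_quo`` — coverage frozen at the 2016 level;
* ``austerity`` — coverage scaled by a common decline-factor path
  calibrated to the forecast federal funding cuts;
* ``austerity_mmp_end`` — as above, with the Mais Medicos contribution
  removed from the termination year onwards;
* ``uhc`` — linear ramp from the 2016 level to 100% coverage in 2030.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import MunicipalPanel

__all__ = [
    "ScenarioSpec",
    "SCENARIO_NAMES",
    "mmp_coverage_contribution",
    "make_decline_path",
    "apply_scenario",
    "default_scenarios",
]

SCENARIO_NAMES = ("status_quo", "austerity", "austerity_mmp_end", "uhc")

#: decline-path anchors implied by the mean-coverage forecasts under the
#: austerity scenario: coverage falls from a mean of 80.4% in 2016 to
#: 66.5% in 2020 and 37.8% in 2030, i.e. relative factors 66.5/80.4 and
#: 37.8/80.4.
DEFAULT_DECLINE_ANCHORS: Mapping[int, float] = {
    2016: 1.0,
    2020: 66.5 / 80.4,
    2030: 37.8 / 80.4,
}

PHYSICIAN_RATIO = 3450  # inhabitants served per Mais Medicos doctor


@dataclass(frozen=True)
class ScenarioSpec:
    """A named coverage-trajectory rule.

    ``decline_factor_path`` (year -> multiplier of 2016 coverage) is
    required for the austerity kinds; ``severity`` is an exponent on the
    log of the path exposed for the sensitivity analysis (>1 = deeper
    cuts).
    """

    name: str
    decline_factor_path: Mapping[int, float] | None = None
    mmp_termination_year: int = 2019
    uhc_target_year: int = 2030
    severity: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in SCENARIO_NAMES:
            raise ValueError(
                f"unknown scenario {self.name!r}; choose from {SCENARIO_NAMES}"
            )
        if self.name in ("austerity", "austerity_mmp_end"):
            if not self.decline_factor_path:
                raise ValueError(f"scenario {self.name!r} needs a decline path")
            years = sorted(self.decline_factor_path)
            vals = [self.decline_factor_path[y] for y in years]
            if any(not (0.0 < v <= 1.0) for v in vals):
                raise ValueError("decline factors must lie in (0, 1]")
            if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
                raise ValueError("decline path must be non-increasing over years")
        if self.severity <= 0:
            raise ValueError("severity must be positive")

    def factor(self, year: int) -> float:
        """Decline factor at ``year`` (log-linear between path years),
        with the severity exponent applied."""
        path = self.decline_factor_path
        years = sorted(path)
        logv = [math.log(path[y]) for y in years]
        base = float(np.interp(year, years, logv))
        return math.exp(self.severity * base)


def mmp_coverage_contribution(doctors, population, total_coverage=None):
    """ESF coverage fraction attributable to Mais Medicos doctors.

    One doctor covers ``PHYSICIAN_RATIO`` inhabitants; the contribution is
    capped by the municipality's total coverage when given and never
    exceeds 1.
    """
    pop = np.asarray(population, dtype=float)
    if (pop <= 0).any() if np.ndim(pop) else pop <= 0:
        raise ValueError("population must be strictly positive")
    contrib = np.minimum(np.asarray(doctors, dtype=float) * PHYSICIAN_RATIO / pop, 1.0)
    if total_coverage is not None:
        contrib = np.minimum(contrib, np.asarray(total_coverage, dtype=float))
    contrib = np.maximum(contrib, 0.0)
    return contrib if np.ndim(doctors) or np.ndim(population) else float(contrib)


def make_decline_path(
    anchors: Mapping[int, float], end_year: int = 2030
) -> dict[int, float]:
    """Log-linear interpolation of relative decline factors between anchors.

    ``anchors`` must include 2016 -> 1.0 and be non-increasing; the
    returned path covers every year from 2016 to ``end_year``.
    """
    if 2016 not in anchors or not math.isclose(anchors[2016], 1.0):
        raise ValueError("anchors must include 2016 -> 1.0")
    years = sorted(anchors)
    vals = [anchors[y] for y in years]
    if any(not (0.0 < v <= 1.0) for v in vals):
        raise ValueError("anchor factors must lie in (0, 1]")
    if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
        raise ValueError("anchor factors must be non-increasing for austerity")
    logv = np.log(vals)
    out = {}
    for year in range(2016, end_year + 1):
        if year >= years[-1]:
            out[year] = float(np.exp(logv[-1]))
        else:
            out[year] = float(np.exp(np.interp(year, years, logv)))
    return out


def apply_scenario(
    panel: MunicipalPanel,
    spec: ScenarioSpec,
    start_year: int = 2017,
    end_year: int = 2030,
    base_year: int = 2016,
) -> pd.DataFrame:
    """Coverage trajectory per municipality under one scenario.

    Returns a tidy frame (muni_id, year, esf_coverage) for
    ``start_year``..``end_year``; all values clipped to [0, 1].
    """
    base = panel.data[panel.data["year"] == base_year]
    if base.empty:
        raise ValueError(f"panel has no rows for base year {base_year}")
    ids = base["muni_id"].to_numpy()
    cov0 = base["esf_coverage"].to_numpy(dtype=float)
    years = np.arange(start_year, end_year + 1)

    if spec.name == "status_quo":
        traj = np.tile(cov0[:, None], (1, years.size))
    elif spec.name == "uhc":
        t_end = spec.uhc_target_year
        frac = np.clip((years - base_year) / (t_end - base_year), 0.0, 1.0)
        traj = cov0[:, None] + frac[None, :] * (1.0 - cov0[:, None])
    elif spec.name in ("austerity", "austerity_mmp_end"):
        factors = np.array([spec.factor(int(y)) for y in years])
        traj = cov0[:, None] * factors[None, :]
        if spec.name == "austerity_mmp_end":
            doctors = base["mmp_doctors"].to_numpy(dtype=float)
            pop = base["population"].to_numpy(dtype=float)
            contrib = mmp_coverage_contribution(doctors, pop, cov0)
            residual = (cov0 - contrib)[:, None] * factors[None, :]
            after = years >= spec.mmp_termination_year
            traj = np.where(after[None, :], residual, traj)
    else:  # pragma: no cover - guarded by ScenarioSpec
        raise ValueError(f"unknown scenario {spec.name!r}")

    traj = np.clip(traj, 0.0, 1.0)
    return pd.DataFrame(
        {
            "muni_id": np.repeat(ids, years.size),
            "year": np.tile(years, ids.size),
            "esf_coverage": traj.reshape(-1),
        }
    )


def default_scenarios(
    severity: float = 1.0,
    mmp_termination_year: int = 2019,
    anchors: Mapping[int, float] | None = None,
) -> dict[str, ScenarioSpec]:
    """The four policy scenarios with the default decline path."""
    path = make_decline_path(dict(anchors or DEFAULT_DECLINE_ANCHORS))
    return {
        "status_quo": ScenarioSpec("status_quo"),
        "austerity": ScenarioSpec(
            "austerity", decline_factor_path=path, severity=severity
        ),
        "austerity_mmp_end": ScenarioSpec(
            "austerity_mmp_end",
            decline_factor_path=path,
            mmp_termination_year=mmp_termination_year,
            severity=severity,
        ),
        "uhc": ScenarioSpec("uhc"),
    }
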