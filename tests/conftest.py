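import numpy as np
import pandas as pd
import pytest

import esfsim as es
from esfsim.config import default_config


@pytest.fixture(scope="session")
def effects():
    return es.default_effect_table()


@pytest.fixture(scope="session")
def small_params():
    return es.CohortParams(n_municipalities=60, master_seed=1)


@pytest.fixture(scope="session")
def small_cohort(small_params):
    return es.generate_full_cohort(small_params)


@pytest.fixture(scope="session")
def big_cohort_panel():
    """Covariate-only cohort large enough for moment checks (no deaths)."""
    params = es.CohortParams(n_municipalities=1500, master_seed=7)
    return es.generate_cohort(params)


@pytest.fixture(scope="session")
def bundle():
    """A small full pipeline run shared across tests."""
    cfg = default_config()
    cfg.cohort.n_municipalities = 200
    cfg.draws.n_draws = 100
    cfg.seed = 11
    return es.run_pipeline(cfg, write=False)


@pytest.fixture
def deterministic_config():
    """Factory for configs with Monte Carlo sampling switched off."""

    def make(n_municipalities=80, seed=5, **overrides):
        cfg = default_config()
        cfg.cohort.n_municipalities = n_municipalities
        cfg.seed = seed
        cfg.draws.n_draws = 1
        cfg.draws.sample_effects = False
        cfg.draws.sample_baseline = False
        for key, value in overrides.items():
            setattr(cfg, key, value)
        return cfg

    return make


def single_muni_panel(
    rate: float = 50.0,
    population: float = 100_000.0,
    years=range(2010, 2017),
    coverage: float = 0.0,
    n_munis: int = 1,
    stratum: str = "acsc_total",
):
    """Minimal panel: all covariates zero, given flat coverage and exact
    expected deaths implied by ``rate`` at gamma = 0."""
    rows = []
    for i in range(n_munis):
        for year in years:
            row = {
                "muni_id": f"T{i:04d}",
                "year": year,
                "population": population,
                "race_mix": 0.5,
                "esf_coverage": coverage,
                "mmp_doctors": 0,
                f"deaths_{stratum}": rate * population / 1e5,
            }
            row.update({c: 0.0 for c in es.COVARIATES})
            rows.append(row)
    return es.MunicipalPanel(pd.DataFrame(rows))


def flat_effects(
    rr_full=0.48, gamma=0.0, stratum="acsc_total", lo=None, hi=None, lag=4
):
    """One-stratum table with zero covariate effects (for closed-form checks)."""
    cov = {name: es.RateRatio(1.0) for name in es.COVARIATES}
    return es.EffectSizeTable(
        strata={
            stratum: es.StratumEffects(
                rr_full=es.RateRatio(rr_full, lo, hi),
                covariates=cov,
                gamma=gamma,
                baseline_rate=50.0,
            )
        },
        duration_lag_years=lag,
    )
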