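# esfsim

Municipal-level microsimulation of primary-healthcare coverage scenarios
and mortality from ambulatory care-sensitive conditions (ACSCs) in
Brazil.

Brazil's *Estratégia Saúde da Família* (ESF) is one of the world's
largest community-based primary-care programmes; its municipal coverage
is threatened by long-term fiscal austerity and by the possible end of
the *Mais Médicos* programme (MMP), which places doctors in underserved
municipalities (one doctor is counted as covering 3,450 inhabitants).
`esfsim` forecasts under-70 ACSC mortality to 2030 for a cohort of
municipalities under four coverage scenarios — status quo, austerity
contraction with and without MMP termination, and expansion to universal
coverage — and propagates parameter and baseline uncertainty by Monte
Carlo. It is aimed at health-policy modellers and epidemiologists who
want a tested, reproducible scenario pipeline with a synthetic-cohort
generator standing in for the restricted municipal panel.

## Model

The expected mortality rate (deaths per 100,000 person-years) of
municipality *i* in year *t* for outcome stratum *s* is log-linear with
municipality fixed effects:

```
rate_ist = exp( α_is + γ_s (t − 2010) + Σ_k ln(β_ks) x_ikt
                + c_it · min(d_it/L, 1) · ln(RR_full,s) )
```

where `α_is` are municipality intercepts anchored on observed deaths,
`γ_s` a secular trend calibrated against an observed national series,
`β_ks` covariate rate ratios (Bolsa Família coverage, poverty,
illiteracy, urbanisation, hospital beds, private insurance, GDP per
capita), `c_it` the ESF coverage fraction, `d_it` years of uninterrupted
programme presence and `L` a duration lag (default 4 years). `RR_full`
is the rate ratio at sustained full coverage; the defaults encode
mortality reductions of 52%, 21% and 15% for nutritional
deficiencies/anaemia, infectious diseases and cardiovascular disease.
Each Monte Carlo draw samples every rate ratio on the log scale with the
variance implied by its 95% CI, redraws baseline deaths as Poisson, and
re-runs the deterministic model along every scenario trajectory; results
are reported as means with 2.5%/97.5% quantiles. Inequality summaries
cover the population-weighted concentration index along the municipal
poverty gradient, poverty-quintile rate differences, and the black/pardo
vs white standardised rate ratio (SRR).

## Worked example

```python
import esfsim as es
from esfsim.config import default_config

cfg = default_config()                 # synthetic cohort, desk scale
cfg.cohort.n_municipalities = 500
cfg.draws.n_draws = 500
cfg.seed = 1
bundle = es.run_pipeline(cfg, write=False)

r = bundle.result
print(es.scenario_ratio(r, "austerity_mmp_end", "status_quo", 2030))
print(es.excess_deaths(r, "austerity_mmp_end", "status_quo"))
```

prints

```
{'ratio': 1.079, 'ci_lo': 1.048, 'ci_hi': 1.109}
{'excess_deaths': 4555.0, 'ci_lo': 2840.0, 'ci_hi': 6218.0}
```

i.e. on this 500-municipality synthetic cohort, contracting ESF coverage
plus MMP termination leaves the mean municipal ACSC mortality rate 7.9%
(95% CI 4.8–10.9%) higher in 2030 than keeping coverage constant, and
costs about 4,600 excess under-70 deaths over 2017–2030. The same run
gives a 2030 black/white SRR 5.5% higher than under the status quo and a
larger mortality concentration among poor municipalities, with the
poorest poverty quintile losing the most (rate difference 6.7 vs 3.0 per
100,000 in the richest quintile). Magnitudes scale with cohort size and
the configured effect table; the cause-specific pass-through (e.g. a 52%
nutritional-mortality reduction at sustained full coverage) is exact by
construction.

A statsmodels-style object API is available for single-stratum work:

```python
model = es.ACSCMortalityModel(bundle.panel, stratum="acsc_total")
res = model.fit()            # anchors fixed effects; optional gamma calibration
print(res.summary())
preds = res.predict()        # deterministic rates 2010-2030
```

The `esfsim` command line mirrors the pipeline:
`esfsim run-all --config config.yaml --n-draws 500 --seed 1 --out out/`
(subcommands `generate`, `forecast`, `scenarios`, `simulate`, `validate`,
`sensitivity`).

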