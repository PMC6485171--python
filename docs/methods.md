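# Methods

## Overview

`esfsim` is a discrete-time, municipality-level microsimulation. It runs
in two stages: (i) construction of a municipal cohort to 2030 — observed
(or synthetic) data to 2016, trend-extrapolated socioeconomic covariates
from 2011, and scenario-driven ESF coverage from 2017 — and (ii)
prediction of ACSC mortality rates from a fixed-effects log-linear rate
model whose coefficients are inputs (rate ratios with 95% CIs), with
Monte Carlo propagation of parameter and baseline uncertainty. The unit
of analysis is the municipality-year; no within-municipality individuals
are simulated.

## The mortality model

For stratum *s* (overall ACSC, three cause groups, two race strata) the
expected rate per 100,000 person-years is

    rate_ist = exp( α_is + γ_s (t − 2010) + Σ_k ln(β_ks) x_ikt + CE_ist )

* **Fixed effects α_is** absorb time-invariant municipal confounding.
  They are *anchored*, not estimated freely: α_is is set so the mean
  predicted log rate over the anchor window (2010–2016) equals the mean
  observed log rate, with a +0.5-death continuity correction applied to
  zero-death years (municipalities with no deaths at all sit at the
  correction floor and are flagged). Anchoring is exact on noise-free
  data. On Poisson data the mean-log anchoring carries the E[ln X] bias
  of about −1/(2μ) per year, negligible when expected counts are large;
  the test suite checks unbiasedness at ~200 expected deaths/year.
* **Secular trend γ_s** (default −0.022/yr, i.e. ≈2.2% annual decline)
  can be calibrated against an observed national series (2010–2015 by
  default): the calibrated γ adds to the current value the OLS slope of
  ln(observed) − ln(predicted) on calendar year. The level is
  deliberately left to the death-count anchoring; calibrating slope and
  level jointly through re-anchored least squares is biased because
  anchoring absorbs part of any trend change. The closed form makes
  calibration exactly idempotent. Observed series may carry a
  multiplicative undernotification correction (≥1) for incomplete vital
  registration; being a constant factor it moves the level, not γ.
* **Covariate effects β_ks** enter as ln(RR) per unit on the scales of
  the covariate table (fractions for coverage/rates, natural logs for
  illiteracy, private insurance and GDP per capita).
* **Coverage effect CE.** Default ("continuous") parameterization:
  coverage × min(duration/L, 1) × ln(RR_full), with L = 4 years and
  duration counting consecutive years of any positive coverage (reset on
  interruption). A "categorical" option for sensitivity work uses three
  coverage-duration classes — none (<70% coverage), consolidating (≥70%
  for fewer than L years, half the log effect), consolidated (≥70% for
  ≥L years, full effect). Both parameterizations interpolate the same
  full-coverage anchors. Optional per-poverty-quintile multipliers scale
  ln(RR_full) for the poverty-stratified-effectiveness sensitivity axis.

### Default effect table

The three cause-group full-coverage rate ratios are fixed anchors: 0.48
(nutritional deficiencies/anaemia), 0.79 (infectious), 0.85
(cardiovascular). The remaining defaults are package choices, made once
and exposed as config inputs, not estimates of any published model:
overall ACSC RR_full 0.85 (0.80–0.90), chosen between the cause-specific
anchors and weighted toward cardiovascular disease, the dominant ACSC
cause group; race-stratum RR_full 0.80 (black/pardo) and 0.89 (white),
encoding the stronger primary-care effect reported for black
populations; covariate RRs of plausible sign and modest size (e.g.
poverty 1.80 per unit fraction, conditional cash transfer coverage 0.92);
baseline 2010 mean rates 100 (overall), 5/20/55 (nutritional/infectious/
cardiovascular), 120/85 (black/white) per 100,000.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis relies on;
it defines the package's study conditions and is first-class, tested
code.

* **Cross-sections.** Each covariate's anchor-year (2015; coverage 2016)
  cross-section is drawn to match configured mean/sd targets exactly in
  distribution: bounded covariates from a logit-normal whose logit-scale
  parameters are solved by Gauss–Hermite quadrature and least squares,
  log-scale covariates from a normal, bed densities from a moment-matched
  log-normal. Infeasible targets (fraction mean outside (0,1), sd above
  the Bernoulli bound) are rejected with a message.
* **Histories.** Around the anchor, covariates follow exact exponential
  trajectories on the natural scale, value(t) = anchor·e^{−λ_i(t−a)},
  with per-municipality λ_i ~ N(λ̄, sd) and multiplicative log-normal
  noise (sd 0.05/yr; the anchor year itself is noise-free so the target
  moments are preserved). Exact exponentials give the trend-fitting
  stage a recoverable ground truth; values are clipped at [0,1] caps in
  the rare tail. ESF coverage instead expands along a logistic path
  (logit-linear growth, ~0.25 logit/yr), reproducing the programme's
  roll-out from near zero in 2000 to a 2016 mean of 80.4% (sd 23.5%).
* **Mais Médicos.** From 2013, doctor counts are Poisson with mean
  scale × population/3450 × exp(strength·(poverty rank − 1)), rank 1 being
  the poorest municipality — doctors concentrate where poverty is high
  (strength 2, scale 0.25 ⇒ mean coverage contribution ≈ 10%).
* **Deaths.** True intercepts α_is are drawn Normal around the stratum
  baseline with a poverty gradient (slope 1.0 on the poverty fraction),
  centred so the 2010 mean rate hits the stratum baseline; deaths are
  Poisson(rate × person-years/10⁵) per stratum (race strata split
  person-years by the municipality's black/pardo fraction), capped at the
  population at risk. An "expected" mode stores noise-free expectations
  for exact-recovery tests.
* **Scale.** Defaults are desk scale: 500 municipalities for tests and
  examples (the full 5,507 is supported), populations log-normal around a
  median of 12,000, constant over the projection (national projections
  are not modelled). Cross-covariate correlations beyond the poverty
  gradients above are not imposed.

What passing tests on this cohort do *not* show: performance on the real
municipal panel, where covariate histories are not exponential, deaths
are overdispersed relative to Poisson, and the effect table comes from a
fitted retrospective model.

## Covariate forecasting

Per municipality and covariate, an exponential trend is fitted by OLS of
log(value − floor) on year over all eleven 2000–2010 points (endpoint
ratios are noise-fragile), and values from 2011 on are replaced by
floor + (level₂₀₁₀ − floor)e^{−λ(t−2010)}, clipped to [floor, cap]. λ may
be negative (growth, e.g. urbanisation) with caps doing the bounding.
Log-scale covariates are exponentiated before fitting and re-logged
after. Bolsa Família coverage is kept observed through 2016 (policy
data) and extrapolated beyond; ESF coverage is left to the scenario
engine. National poverty calibration multiplies every municipality's
value by target/current population-weighted mean (proportional
allocation — the allocation rule is a package choice), iterated to a
fixed point so clipping cannot leave the mean short and the operation is
idempotent; the default recession path interpolates 13.8% (2015), 18.4%
(2020), 12.0% (2030).

## Scenarios

All four scenarios transform the 2016 coverage: status quo freezes it
(and, by construction, programme effectiveness); austerity multiplies it
by a common decline-factor path, log-linearly interpolated between
anchors 1.0 (2016), 66.5/80.4 (2020), 37.8/80.4 (2030) — the decline in
mean coverage implied by forecast federal funding cuts — with a severity
exponent on the log path as the sensitivity dial; austerity+MMP-end
additionally removes the municipality's MMP contribution
(min(doctors×3450/population, coverage)) instantaneously at the
termination year (2019; no phase-out profile is modelled) before
applying the decline to the residual; UHC ramps linearly to 100% in
2030. The decline multiplier applies to total coverage (including any
MMP share) in the austerity-with-MMP scenario. These choices guarantee
the pointwise dominance uhc ≥ status quo ≥ austerity ≥ austerity+MMP-end,
which the model's monotonicity turns into the corresponding mortality
ordering.

## Monte Carlo engine

Per draw: every rate ratio is sampled as ln RR ~ N(ln point, σ) with
σ = (ln hi − ln lo)/(2·1.96) (log scale keeps RRs positive; natural-scale
sampling is available by flag since the distributional scale is a
modelling choice); baseline deaths over the anchor window are resampled
Poisson around the observed counts and the fixed effects re-anchored;
the deterministic model then runs along every scenario trajectory.
Draws are independent (seed-sequence spawning) and the whole pipeline is
deterministic given the master seed. Summaries are means and 2.5%/97.5%
quantiles over draws. "Mean municipal rate" is the unweighted mean over
municipalities (population-weighted means are stored too); excess deaths
are population-weighted by construction, summing (rate_a − rate_b) ×
person-years/10⁵ over municipalities and years (2017 on by default).
Scenario ratios are summarised as the mean of per-draw ratios, so
reciprocity holds draw by draw; draws with zero denominators are
excluded with a warning. Defaults: 500 draws for desk scale; the
full-scale setting is 10,000.

## Inequality metrics

* **Poverty quintiles**: municipalities are split into five equal-count
  groups by 2010 poverty (quintile 1 poorest, ties broken by stable id
  order) and the assignment is frozen thereafter.
* **Concentration index**: C = 2·cov_w(y, R)/μ with population weights
  and weighted fractional ranks running from poorest (0) to richest (1);
  C < 0 means mortality concentrated among poorer municipalities. The
  formula is the standard health-economics form; ranking direction and
  weighting are documented choices.
* **SRR**: per draw, mean municipal black/pardo rate divided by the
  white rate. Age structure is not modelled, so the ratio of predicted
  stratum rates stands in for an age-standardised ratio.

## Validation and sensitivity

Internal validation refits the generating regression — municipality
intercepts, the covariates, a linear time trend and the consolidated
coverage term (coverage × ramp), with log person-years offset — on a
simulated panel (2017–2030 by default) and reports the maximum deviation
of fitted coefficients from the inputs plus Wald CIs. The fixed-effects
Poisson MLE is computed by a Newton solver that profiles out the
intercepts analytically and uses the Schur-complement profile Hessian,
which is identical to the dummy-variable GLM (cross-checked against
statsmodels in the tests) at a fraction of the cost; columns are
standardised internally, within-group-constant columns are rejected as
collinear with the intercepts, all-zero municipalities are dropped and
reported, and steps are damped with a trust region. External validation
regresses an observed national series on predicted rates (slope,
intercept, R², share of observations inside the credible band); any
observed series can be supplied as year→rate.

The sensitivity harness reruns the pipeline over variants along five
axes (decline severity, duration-effect form, poverty-stratified
effectiveness, recession path, secular trend) with one shared synthetic
cohort — the axes vary the analysis, not the data — and tabulates the
headline outputs per variant; failing variants are reported, never
dropped. Two structural facts are exploited as checks: excess deaths
increase monotonically in decline severity, and a trend shift common to
all scenarios cancels exactly from scenario rate ratios.

## Numerical choices and limitations

Rates are per 100,000 person-years throughout; coverage is a fraction
internally. Logit-normal moment matching uses 80-node Gauss–Hermite
quadrature and rejects unattainable targets. The quintile aggregation is
skipped (not NaN-filled) when a cohort is too small to populate all five
quintiles. Reported problem sizes in tests (60–500 municipalities,
up to 500 draws; 200 replicates for the coverage study) were chosen as
the smallest giving stable qualitative behaviour. Known limitations:
Poisson (not negative-binomial) death counts; no age structure; no
migration or population growth; MMP doctors constant from 2013; the
synthetic correlation structure is simpler than the real panel's.
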