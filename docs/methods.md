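# Methods

## The estimand and the design

The package treats the nationwide cancellation of parkrun events
(21 March 2020 – 23 July 2021 inclusive; events resumed Saturday
24 July 2021) as the interruption in an interrupted time-series design on
weekly finisher counts. Two quantities describe the lasting effect: the
step change — the ratio of participation just after reopening to what the
extrapolated pre-interruption trend predicts for the same weeks — and the
change in trend — how post-reopening growth differs from pre-interruption
growth. Because there is no unexposed control population, the
pre-interruption model extrapolated over the whole window serves as the
counterfactual; this identifies the effect only insofar as the pre-2020
trend would have continued, which is the design's central assumption.

## Model

For each stratum (five IMD quintiles and their total) the weekly count
y_w is modelled as quasi-Poisson with log link and population offset:

    log mu_w = log(pop/1000) + b0 + b1*t + b2*t^2
               + sigma_w*(b4 + b5*T + b6*T^2) + gamma_season(w)
    Var(y_w) = phi * mu_w

Parameters, units and defaults:

* **t** — years since the window start; one week = 1/52.1775 years, so
  exp(b1) is the pre-interruption growth rate ratio *per year*. Fitting on
  a weekly time scale and annualising via exp(52.1775 * b_week) is
  numerically identical; the years scale is used internally so coefficients
  exponentiate directly to the reported table.
* **b2** (quadratic damping) — pre-interruption growth is near-linear but
  cannot grow forever; the quadratic lets the growth rate decline smoothly
  (an S-curve approximation over the observed range).
* **sigma_w** — 0/1 indicator from the reopening Saturday; exp(b4) is the
  step-change rate ratio. **T** — years since reopening (0 before), giving
  the post-reopening change in linear (b5) and quadratic (b6) trend.
* **Seasonality** — a 13-level categorical: level = floor((day_of_year−1)/28)
  capped at 12, plus 1. Levels 1–12 are exact four-week blocks anchored at
  1 January; level 13 absorbs the final 29–30 days. Level 1 is the
  reference. The anchor is a design choice — any fixed anchor yields an
  equivalent model up to relabelling.
* **phi** — Pearson dispersion, chi-square / (n − p), estimated after the
  Poisson IRLS fit and applied multiplicatively to the covariance.
  Intervals are Wald with z = 1.96; quasi-likelihood point estimates equal
  ordinary Poisson MLEs.

Week 0 of the study window is the first Saturday on/after 1 January 2015
(2015-01-03); every count is attached to its event Saturday, and period
boundaries given as mid-week dates bind at the following Saturday.

## Handling the all-zero gap

Every week in [2020-03-21, 2021-07-24) has exactly zero finishers. A free
gap-level coefficient therefore has no finite MLE (perfect separation: the
likelihood increases monotonically as it goes to −∞). Estimation excludes
the gap rows, which gives the same remaining coefficients as keeping them
with the gap effect pinned at any sufficiently negative value; the test
suite asserts agreement to 1e−6 against a fit with the gap effect fixed at
−20 on the log scale. The gap-level coefficient is reported as not
estimable rather than as a number.

Degenerate design columns (identically zero on the estimation rows, e.g.
the post-reopening terms when a window ends before reopening) are dropped
and recorded on the fit; genuine collinearity among informative columns
raises an error naming the columns.

## Counterfactual and accounting

The counterfactual sets sigma = 0 (and T = 0) for every week and predicts
with full seasonality and offset; on pre-gap weeks it coincides with the
ordinary fitted values by construction. "Trend" curves average seasonality
out multiplicatively: the weekly seasonal multipliers exp(gamma_l) are
averaged over the 13 levels weighted by the number of window weeks each
level covers, so the trend line is the seasonal prediction with the
season factor replaced by its window mean. Lost finishes per period are
the sum over member weeks (membership by Saturday date, half-open
[start, end)) of counterfactual minus observed counts; percentage decrease
is that difference over the counterfactual total. Weekly shortfalls sum
exactly to period differences, and disjoint periods sum exactly to their
union row. Counterfactual totals are kept as reals and rounded only for
display. The crossover date compares the season-averaged post-reopening
curve with the season-averaged counterfactual — the seasonal and baseline
factors cancel, so it is the first week with b4 + b5*T + b6*T^2 >= 0,
scanned weekly over a 5-year horizon past reopening.

No uncertainty intervals are attached to lost-finish totals or the
crossover date; they are point summaries of the fitted curves.

## Synthetic data generator

`synthetic_data` draws weekly counts from the same model the estimator
fits, with means computed through the estimator's own design constructor
so generator and fit share covariates exactly. Counts are
negative-binomial with mean mu and variance phi*mu (gamma-Poisson mixture,
shape mu/(phi−1)); quasi-Poisson prescribes only a variance function, and
this is the standard generative stand-in, degenerating to Poisson at
phi = 1. Gap weeks are exactly zero. Strata are independent, and the total
stratum is the sum of the quintile draws — the same conservation the
ingest path enforces.

The default scenario (`make_default_scenario`) fixes: 425 weeks from
2015-01-03; gap 2020-03-21 / 2021-07-24; generating rate ratios equal to
the headline total-population estimates from the open dataset (1.34 per
year pre-trend, 0.98 damping, 0.71 step, 0.76 and 1.21 trend change);
dispersion phi = 3; five strata of 11.2 million residents (England's
population split into quintiles) with baseline weekly rates of 0.35, 0.70,
1.10, 1.50 and 2.10 finishes per 1000 residents, increasing with
affluence — the magnitude and quintile ordering seen in the real series in
early 2015; and mild seasonal multipliers within ±12% of the reference.
These values were chosen once as the canonical test conditions.

What the generator does **not** emulate: LSOA-level micro-structure
(counts are drawn at stratum level, not summed over 32k areas);
weather-related event cancellations (occasional sharp one-week dips in the
real series); serial correlation (weeks are independent given the mean);
secular confounders such as cost-of-living changes; and the much larger
dispersion of the real national series, where week-to-week variation far
exceeds phi = 3. Passing recovery tests therefore show the estimator is
correct when its model is correct — unbiased rate-ratio recovery and
honest Wald coverage — not that the model captures every feature of the
real data; on the real series the residual diagnostics (Pearson/deviance
residual plots, lag-1 autocorrelation) are the relevant check.

## Numerical choices

* IRLS convergence: relative deviance change < 1e−8, at most 100
  iterations; non-convergence is flagged on the fit rather than raised.
* Dispersion is computed after the fit from the Pearson chi-square; a
  saturated fit yields phi = 0 and zero-width intervals rather than a
  division failure.
* The tests' independent oracle maximises the Poisson log-likelihood
  directly by damped Newton iteration on the analytic gradient and
  Hessian, sharing no code with the GLM path; IRLS must agree to 1e−6.
* Recovery tests use 200 replicates of the default scenario; the
  brute-force oracle checks use series of at most 50 weeks and 4
  parameters, where direct maximisation is exact to machine precision.
* Display rounding: rate ratios and intervals to 2 dp, percentages to
  1 dp, counts to integers — applied only at the output layer.

## Ingest conventions and limitations

Areas missing either deprivation or population are excluded (not imputed)
and tallied; IMD deciles collapse to quintiles by ceil(d/2), and if only
scores are supplied deciles are assigned by ranking areas (highest score =
most deprived = decile 1). Missing weeks inside the window are zero-filled
so genuine shutdown zeros and accidental data holes look identical in the
series — the per-stratum zero-week count is logged so holes are visible.
Population and deprivation are held constant across the window. Upstream
exclusions in the source extract (junior events, non-Saturday events,
custodial sites, non-England areas) are assumed already applied and are
not re-derivable from aggregated data.

Known limitations: Wald intervals ignore residual autocorrelation
(Newey–West or negative-binomial alternatives are out of scope); the
counterfactual inherits all uncertainty of a 14-month extrapolation; and
the analysis is ecological — aggregated counts support no individual-level
conclusions.
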