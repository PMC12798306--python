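# Methods

This note documents the models, defaults and design choices behind `bisim`,
and what the synthetic-data tests do and do not establish about real data.

## 1. Synthetic survey data

Two generators stand in for the licensed microdata.

**Cross-section** (`gen_cross_section`).  Households are built from
marginal distributions only: counts of adults (18+) and children (0–13)
with means calibrated to 1.78 adults and 0.33 children per household; adult
age bands, sex, region, tenure and education drawn from published survey
margins.  No joint (census-style) calibration is attempted — marginal
realism is sufficient to exercise every downstream computation.  Household
members aged 14–17 are not generated, so the OECD adult count (14+) equals
the count of 18+ members; the equivalence-scale code nevertheless implements
the full 14+ rule for user-supplied data.  Gross monthly earnings for
employed adults are log-normal (log-mean 7.618, log-sd 0.5); a 64% employment
rate among the working-age, 10% among 65+.  Adult grossing weights are
uniform and normalised to a configurable adult-population total (default
53 million).

**Panel** (`gen_panel`).  Log net equivalised monthly income for person *i*
at wave *t* is `m_i + u_it` with a persistent person mean
`m_i ~ N(7.618, 0.5²)` and an AR(1) transitory deviation (persistence 0.5,
stationary sd 0.3).  This gives distinct, controllable within/between
variance shares — exactly what the within-between estimator needs to be
identified.  Health scores follow the linear model

    y_it = α + β_w (x_it − x̄_i) + β_b x̄_i + controls + λ(y_{i,t−1} − μ_i) + a_i + e_it

with defaults β_b = 2.0 / 1.5 and β_w = 1.0 / 0.8 score points per log-£
(MCS / PCS), person effect sd 6, occasion sd 7, λ = 0, intercepts placing
the score means near 50.  The generator uses the *empirical* person mean
x̄_i, matching the estimator's decomposition, so noise-free recovery is an
exact linear-algebra identity.  Scores are clipped to the instrument range
[0, 100]; the clipping rate is monitored in tests and stays well below 1%.
Lagged case indicators (MCS ≤ 45.6 / PCS ≤ 50 at the previous wave) are
seeded from an internal burn-in wave so wave 1 has a defined lag.  Attrition,
when enabled, is independent per wave after wave 1 — the study design
controls for attrition but its process is not public, so independence is the
simplest explicit assumption; `make_balanced` keeps only complete cases.

What passing tests show: the estimator, forecast and valuation stages are
correct *given* the model they assume.  What they do not show: robustness to
real-survey features absent here — measurement error in SF-12, informative
attrition, joint demographic structure, income under-reporting, survey
design effects.

## 2. Tax-benefit calculator

A deliberately stylised system, parameterised in `TaxBenParams`, not a
statutory model: one income-tax schedule (personal allowance £12,570, rates
20/40/45%), one NI schedule (12%/2%), Child Benefit (£24.00 first /
£15.90 subsequent child per week), State Pension (£185.15/week from 65),
and Universal Credit with a single/couple allowance table (£334.91/£525.72
per month), £244.58 child element, 55% taper on net earnings above a £300
work allowance, full take-up by default (partial take-up is an independent
seeded Bernoulli per entitled household).  Weekly amounts convert at ×52/12.
Incomes are monthly, before housing costs.

One deliberate rule: **all benefit income other than UC itself (Child
Benefit, State Pension — and Basic Income net of its disregard, under
reform) counts as unearned income in the UC means test.**  With that rule
the Basic Income replacement is exactly one-for-one for UC recipients, and
with a positive disregard every baseline UC recipient gains at least the
disregard — the two properties that define how these schemes are meant to
interact with means-testing.  The disregard defaults to £10/month per
benefit unit for schemes 1–2 ("small" is the only public guidance) and 0
for scheme 3, whose payments are large enough to exhaust UC anyway.

The pension age is fixed at 65 to align with the schemes' 65+ band.  An
optional funding adjustment adds a flat percentage-point rise to all income
tax rates under reform; default off (schemes 2–3 are deliberately not
fiscally balanced, and funding design is out of scope).  Costs are static:
no behavioural response.

Distributional statistics: weighted Gini via the midpoint-rank formula
(algebraically identical to the pairwise mean-absolute-difference
definition), baseline-income quintile gains, winners/losers bands, poverty
headcounts below 60% of the weighted median equivalised income (note the
relative line moves with the median, so headline relative poverty can rise
even when every household gains; the tests check the anchored rate), and
the aggregate static exchequer cost.

## 3. Within-between estimation

Income is decomposed into the person mean of log income (`x_between`) and
the deviation from it (`x_within`); a £1 floor precedes the log.  Both
components enter one equation together with the controls — the Mundlak
formulation, whose random-effects fit is the textbook within-between
estimator.  The log transform is the default because the income-health
literature this design follows treats the effect of income as positive and
concave; `linear` is available in config.

The random-effects fit is balanced-panel feasible GLS: variance components
from pooled-OLS residuals (Swamy–Arora), quasi-demeaning weight
θ = 1 − √(σ²_e / (σ²_e + Tσ²_a)), then OLS on the transformed data.  When
σ̂²_e ≈ 0 (noise-free data) θ is set to 0 and the fit reduces to exact OLS.
A pooled-OLS estimator with person-clustered (CR1) standard errors is the
built-in cross-check; a mixed-model fit (statsmodels MixedLM) is used as an
independent oracle in the test suite.  Rank deficiency raises an error
naming the offending columns (QR with column pivoting); a panel with zero
within-person income variance reports β_w as NaN — undefined, never zero.

**Bootstrap.**  Persons are the resampling unit — all of a person's waves
move together, matching the panel's dependence structure.  θ is held at its
full-sample estimate across replicates; each replicate then solves the
normal equations assembled from per-person Gram blocks weighted by
multinomial resampling counts, which is algebraically identical to
refitting the fixed-θ GLS on the stacked resampled rows and makes a
1,000-replicate bootstrap essentially free.  Intervals are percentile
(2.5/97.5); the bootstrap distribution of the between-coefficient is close
to symmetric here, so percentile and normal intervals nearly coincide.
Replicates with singular designs (possible when a rare categorical level
draws zero persons) are dropped and counted; more than 5% dropped is an
error rather than a silently degraded interval.

When the lagged case indicator is included, each person's first wave is
dropped (the lag is undefined there), keeping the panel balanced at T−1.
The ground-truth recovery benchmarks run the specification *without* the
lagged indicator: conditioning on an outcome-derived lag when the
generating process has no state dependence partially absorbs the person
effect and would bias the between-coefficient, so the correct benchmark is
the generating specification.  The indicator itself is implemented and
tested for real-data use, where state dependence is plausible.

Verified performance (defaults, 2,000 persons × 12 waves): the point
estimator is unbiased (mean estimate 2.005, truth 2.0, 250 replicates);
the empirical sampling sd (0.248) is slightly below the mean analytic
clustered SE (0.273); percentile-bootstrap coverage of the 95% CI is ≈0.93
across 100-replicate simulation blocks.

## 4. Health impact

The cross-section carries no SF-12 scores, so baseline MCS/PCS are imputed:
linear predictor from the fitted coefficients (evaluated at baseline log
income, x_within = 0, plus the fitted control effects) plus a seeded
N(0, σ²) draw, clipped to [0, 100].  σ defaults to 9 score points,
consistent with SF-12 population sds.  The bridge is explicit and seeded so
its contribution can be sensitivity-tested; it is *not* folded into the
confidence intervals, which propagate coefficient uncertainty only: each
bootstrap replicate's between-coefficient rescales the score changes with
the imputation draws held fixed, and prevented-case counts are recomputed.
The same imputation seed is shared across schemes within a run, so scheme
comparisons see identical baseline populations — this is what makes
prevented cases monotone in scheme generosity.

Score changes use the between-coefficient only (permanent income change);
cases are counted at MCS ≤ 45.6 and PCS ≤ 50 with weighted sums; "prevented
or postponed" is the net annual difference (cures minus new cases), which
equals person-level transition accounting by construction and is
regression-tested against it.

## 5. Valuation

**SF-6D crosswalk.**  The licensed SF-12→SF-6D scoring algorithm cannot be
shipped, so utility changes use a transparent linear crosswalk
Δu = 0.009·ΔMCS + 0.007·ΔPCS, with the intercept calibrated so the
reference panel means (MCS 50.47, PCS 50.18, SF-6D 0.7857) are jointly
consistent; floor 0.345 (the published SF-6D(SF-12) worst state), ceiling
1.0, with clamping applied when baseline utilities are tracked.  The
crosswalk is a config object — swap in any published tariff.

**QALYs and value.**  QALYs/year = Σ weight × Δu over the grossed reform
population; multi-year totals multiply by years in operation (no
discounting — impacts are treated as annual).  Value: £30,000/QALY (NICE
upper threshold); the Green Book £70,000 variant is the ×2.33 multiplier.
Grossing uses the reform (cross-section) population weights; the estimation
panel's weights play no role in aggregation.

**Years of life gained.**  Per-person QALY gains times a sex × age-band
multiplier table.  The shipped table is synthetic: a declining-with-age
shape (younger people convert a QALY into more expected life-years), scaled
at construction so the cross-section-age-mix-weighted mean equals the ≈1.31
years-per-QALY anchor implied by the reference headline figures; a ±3% sex
adjustment.  Supply the real multiplier table where licensed.

**Cost savings.**  savings = prevented depression cases × 50% treated ×
unit cost × CPI factor, per perspective.  The trial-derived unit costs
behind the published estimates are not public; defaults are back-derived
from the published tables (savings ÷ treated cases, averaged across the
three schemes: ≈£2,040 NHS/PSS, ≈£9,105 total per treated case per year,
agreeing across schemes within ±1%).  The 50% treated assumption applies to
costs only — never to case counts or QALYs.  Physical-health savings are
refused by design: no defensible public unit cost exists, and the
conservative choice is to omit them.

## 6. Pipeline, seeds, caching

One master seed spawns four recorded sub-seeds (cross-section, panel,
bootstrap, imputation); identical config + seed ⇒ hash-identical tables.
The coefficient fit — the expensive stage — is cached keyed by the config
hash when an output directory is given.  Reports validate
lower ≤ central ≤ upper in every row at write time.

Problem sizes used by the test suite and acceptance script — 2,000-person
panels, 2,000-household cross-sections, 200 bootstrap replicates for
simulation studies (1,000 for single fits) — were chosen to put Monte Carlo
error well inside the tolerances being asserted while keeping a full run in
the low minutes on one CPU.

## 7. Known limitations

- The tax-benefit system is stylised: no council tax, housing benefit,
  indirect taxes, sanctions, or behavioural labour-supply response.
- The estimation design supports the within-between causal argument only;
  no quasi-experimental identification.
- The synthetic generator's marginals-only realism means distributional
  results (Gini, poverty) characterise the pipeline, not the UK.
- QALY aggregation assumes the fitted between-coefficient applies uniformly
  across the income distribution; published evidence suggests diminishing
  and possibly negative effects at the very top, which a log transform
  attenuates but does not eliminate.
- CI coverage is mildly below nominal (~0.93 vs 0.95) — typical for
  percentile bootstrap at this scale; users wanting exact-coverage
  intervals can raise `bootstrap_reps` and/or use the clustered-SE normal
  intervals also reported.
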