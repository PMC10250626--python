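# Methods

## The model

`t2dms` implements an irreversible illness–death model for pharmacologically
treated type 2 diabetes (T2D): three states — free of T2D, living with T2D,
dead — with annual transition probabilities

* `p_inc(a, g, q, y)` — P(free → T2D within the year),
* `p_mF(a, g, q, y)` — P(free → dead),
* `p_mT(a, g, q, y)` — P(T2D → dead),

specific to age `a` (30–100), gender `g`, equivalised-household-income
quintile `q` (Q1 = highest income, Q5 = most deprived) and calendar year
`y`. A deterministic cohort-component engine advances expected
state-occupancy counts one year at a time: with start-of-year counts
`N_free`, `N_t2d`,

```
deaths_free = N_free · p_mF        incident = N_free · p_inc
deaths_t2d  = N_t2d · p_mT
N_free(a+1, y+1) = N_free − deaths_free − incident
N_t2d(a+1, y+1)  = N_t2d − deaths_t2d + incident
```

A cohort of disease-free 30-year-olds enters every year. Age 100 closes the
life table (`p_mF = p_mT = 1`). There is no recovery and no migration.

**Timing convention.** State is evaluated at the start of each calendar
year. A person whose first qualifying register entry falls in year `t`
spends year `t` at risk in the free state and occupies the T2D state from
`t + 1`; they are not exposed to T2D mortality in year `t`. Within a year,
death is resolved before incidence, so a death in the incidence year is a
free-state death and no incidence event is counted. One convention had to
be fixed for the generator, the occurrence/exposure bookkeeping and the
engine to be mutually unbiased; this is the one used everywhere.

## Synthetic register

Real medication-reimbursement registers are licensed and cannot ship with
code, so estimation runs against a generated register with a known
parametric ground truth (`GroundTruthSchedule`). What it emulates:

* **Incidence** log-Gaussian in age, peaking after 60 (2 years earlier per
  quintile step toward deprivation — deprived groups develop T2D at
  earlier ages), higher in men, with a log-linear income gradient
  (Q5:Q1 ≈ 1.7). Calendar effects: a mild pre-2007 rise, a 2007–2010
  diagnosis-surge bump (multiplier 1.25, the analogue of a national
  diabetes-awareness programme) and a post-2011 decline of 1 %/yr.
* **Mortality** Gompertz in age (slope 0.093/yr), an income gradient
  (Q5:Q1 ≈ 1.4 at midlife) fading linearly to zero by age 95 (old-age
  mortality convergence), declining 2 %/yr in calendar time.
* **T2D excess mortality** multiplicative, `1 + 2·exp(−(a−30)/30)`:
  roughly 3-fold at 30, 1.6 at 65, fading with age.
* **Demography** ~100k persons (configurable) aged 30+ in 1995 with a
  baby-boom bulge at ages 45–50, plus 30-year-old entrant cohorts of 2.1 %
  of the initial population per year (the Finnish 1965–89 birth cohorts
  relative to the 3.6 M residents aged 30+). These rates keep the
  population roughly stationary, as in the official projections the real
  analysis used for its entrant vector.
* **Income** log-normal equivalised income; each person keeps a fixed
  percentile within their quintile band, incomes grow 1.5 %/yr, household
  composition is drawn once per person. Annual ranking within 5-year age
  strata therefore recovers the planted quintile up to boundary noise.
* **Medication histories** are written so that the five ascertainment
  criteria recover the simulated disease state exactly, with cases routed
  through all five criteria (configurable shares) and a 1 % "decoy"
  insulin-only subpopulation that must *not* be ascertained.

What it does **not** emulate: under-ascertainment (every true case is
recoverable from its purchase history — the built-in validation MAPE of
~0 demonstrates internal consistency, not real-world sensitivity), income
mobility (quintile fixed at entry, matching the source model's
assumption), duration effects of T2D on mortality, migration, and
household dynamics beyond the OECD-modified scale arithmetic
(1.0 / 0.5 / 0.3 for first adult / other adults / children). Passing tests
therefore show the estimation and projection machinery is correct under
the stated model, not that the model captures every feature of register
data.

## Case ascertainment

A person is classified as having pharmacologically treated T2D if any of:

1. special reimbursement granted with a T2D diagnosis;
2. any purchase in the insulin-secretion-stimulating ATC classes A10BB,
   A10BH, A10BX02, A10BX03, A10BX04;
3. more calendar years with any blood-glucose-lowering (A10B) purchases
   than years with insulin (A10A) purchases;
4. equally many A10B and insulin years and age ≥ 40 at first purchase;
5. special reimbursement with unspecified diabetes diagnosis at age ≥ 40.

The incidence year is the earliest register entry; the reported criterion
is the smallest qualifying number. Insulin is taken as ATC class A10A for
the year-counting in criteria 3–4.

## Estimation and projection

* **Occurrence/exposure estimates.** `p̂ = events / start-of-year persons
  at risk` per cell; cells with no exposure are missing.
* **Age smoothing.** Within gender × quintile × year, cells with ≥ 500
  at-risk persons anchor a monotonicity-preserving PCHIP interpolant on
  the logit scale; sparse and missing cells are read off the interpolant
  (linear logit extrapolation beyond the anchor range). Strata still
  missing afterwards borrow NaN-aware means over quintiles, then genders,
  then years.
* **Mortality trend.** Per gender × quintile, the log of the
  exposure-weighted mean mortality (fixed, time-averaged age weights, ages
  ≤ 89 — the terminal age and near-saturated cells carry no trend) is fit
  over 1995–2018 with a penalized B-spline smooth (statsmodels `GLMGam`,
  Gaussian on the log scale, df 5, fixed penalty; log-linear fallback on
  degenerate fits). The extrapolation slope is the least-squares slope of
  the fitted smooth over the whole window — penalized splines flatten at
  the boundary, so a short end-window slope is biased toward zero under
  noise. Each age cell's projection scales a trend-aligned mean of its
  last 5 observed values. The T2D:non-T2D mortality ratio is frozen at its
  fitted 2019 value per stratum, keeping differentials constant at 2019
  levels. A 10-year-age-band option (`band_width`) exists for
  register-scale data; at the shipped sample sizes band-level series carry
  too few events to identify ~1–2 %/yr slopes, so the default pools ages.
* **Incidence, baseline.** Frozen at the 2019 level for 2020–2040; the
  2019 level itself is a trend-aligned mean of 2015–2019 (a single year's
  cell estimates are too noisy to anchor a 20-year projection).
* **Incidence, scenario A.** Log-linear continuation of the 2011–2019
  decline, slope pooled over ages and quintiles within gender (levels stay
  fully stratum-specific); 2007–2010 is excluded from fitting wherever the
  window touches it. A rising fitted slope is allowed but logged.
* **Scenarios B and C.** Levin's population attributable fraction
  `PAF = p·(RR−1) / (1 + p·(RR−1))`, computed separately for the incidence
  and mortality relative risks per gender, constant across income groups.
  B multiplies scenario A's post-2019 `p_inc` and `p_mT` by `1 − PAF`
  (obesity excess risk eliminated), C by `1 + PAF` (contribution of
  obesity doubled). Shipped assumptions (`p_ob = 0.25`, `RR_inc = 3.0`,
  `RR_mort = 1.5`) are labelled illustrative defaults; every output
  carries the assumption label.
* **Constraint handling.** Probabilities are clamped to `[1e-8, 1−1e-8]`;
  where `p_inc + p_mF > 1` after smoothing or projection both are rescaled
  proportionally to sum 0.999.

## Health expectancy at 65

For each calendar year's schedule (period, not cohort), a synthetic cohort
starts at age 65 with the *projected prevalence mix* of that stratum-year —
so LE-with-T2D reflects pre-65 onset as well as post-65 incidence — and is
pushed through the same update rule as the engine. Person-years accrue
with `a_x = 0.5`: half-year credit in the year of death, and the year of
T2D onset split half-and-half between the states. By construction
`LE_with + LE_without = TLE65` exactly. With constant hazard `q` and no
incidence the chain has the closed form
`TLE65 = (1 − q/2)/q · (1 − (1−q)^{35}) + 0.5·(1−q)^{35}` (terminal age
100; 4.5 − 4·0.8³⁵ at q = 0.2), which the tests pin exactly.

## Validation and the microsimulation oracle

`microsim_oracle` replays the engine's dynamics with individual Bernoulli
draws; the deterministic projection is its expectation, and the suite
checks agreement within 3 Monte-Carlo standard errors at 10⁵ agents.
`validate_against_reference` compares any (year, value) series against
user-supplied CSVs shaped like Human Mortality Database or
Diabetes-in-Finland extracts (never downloaded); in the shipped pipeline
the reference is the generator's ground truth.

## Problem sizes and numerical choices

Default runs use 100 000 initial persons (≈ 2.7 M person-years over
1995–2019); the test suite's statistical checks run at this size and its
mechanical checks at 3–4 000 persons. At 10⁵ persons an ideal log-linear
fit of the 2011–2019 incidence window still carries a slope standard error
of ≈ 0.5 %/yr — about 10 % at 2040 after 21 years of extrapolation — so
trend-recovery is asserted exactly on noiseless planted schedules
(machinery correctness) and at 5 % only for mortality, whose 24-year
window supports it. Scenario orderings (B < A < baseline < C) are the
noise-robust signature of the incidence trend and are asserted on the
estimated pipeline. All randomness flows from a single config seed;
identical config and seed reproduce every output byte for byte.

## Known limitations

* The 1995 register start left-truncates history: persons already
  prevalent in 1995 are dated to their first in-window entry, so 1995
  estimates carry a wash-in artifact (trend windows start later).
* Quintile boundaries in tiny oldest-age strata (a handful of persons)
  cannot reproduce exact fifths; mismatches against the planted quintile
  are rare and confined there.
* No uncertainty intervals on projections (point projections only, as in
  the source analysis).
* Scenario multipliers apply uniformly across income groups; no
  income-specific obesity exposure is modelled.
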