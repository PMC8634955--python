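# Methods

## Model structure

The population is a deterministic system of difference equations over
stocks indexed by gender, single year of age (0–100, integer completed
years), joint product-use state and quit-time bin.  A joint state is one
never/current/former status per product; with `N` products there are
`3^N` states.  Product index 0 is, by convention, the combustible
cigarette.  From every stock, each non-empty subset of products may
simultaneously perform its single admissible move (never→current,
current→former, former→current), which yields `3^N (2^N − 1)` potential
flows — 3, 27 and 189 for one, two and three products, i.e. `2^N − 1`
outflows per stock.  The multi-product ("simultaneous move") flows are
enumerated because they are part of the structural combinatorics, but
default rate tables give them zero probability; nothing in the engine
depends on them being zero.

Counts are continuous (fractional persons).  The model is not an
individual-level simulation; identical inputs always produce identical
trajectories, and the only randomness anywhere in the package is the
explicit CI-resampling of the sensitivity module and the seeded noise in
the fixture generator.

## Time step

A calendar year labels the population at 1 January.  One step, in a
fixed audited order:

1. **Mortality.**  Each cell dies at `clip(m_never(g,a,y) · RR(cell), 0, 1)`
   with the age-100 rate forced to 1, so the top cohort always empties
   through the death ledger.
2. **Transitions.**  Every flow's annual probability is applied to the
   post-mortality stock simultaneously (one Markov-style step from the
   same snapshot).  If a stock's outflow means sum to `S > 1` they are
   rescaled by `1/S` (logged); gating and the initiation decline are
   applied before this normalization.
3. **Aging.**  A pure shift by one year of age; quit-time bins advance
   in the same sub-step (see below).
4. **Births** enter at age 0, all-never, split by gender.
5. **Net migration** is allocated over ages by the input distribution;
   migrants copy the resident product-status mix of their (gender, age)
   cell (a neutral choice that leaves prevalence unchanged; the sources
   this model is built for publish no migrant smoking data).  Removals
   exceeding a cell clamp it to zero with a logged warning.

Totals reconcile every year: `pop' = pop − deaths + births + migration`
to ≤ 1e-9 relative (the engine logs any violation; in practice residuals
sit at machine precision).

## Quit-time clock

Former smokers are binned by years abstinent: 1–20 and a combined 20+
group.  Internally there is a transient bin 0: a smoker quitting during
year *t* sits in bin 0 until the aging sub-step and therefore starts
year *t+1* in bin 1.  Bin 0 is also the only occupied slot for states
whose cigarette status is not FORMER.  Relapse empties the clock
(whatever the bin, a relapser returns to bin 0 of the current-smoker
state) and its probability declines with time abstinent through a
per-bin multiplier vector, by default geometric with ratio 0.85 per year
(the source literature reports long-term relapse decline but no usable
table, so the vector is configurable input).

## Mortality stratification

Current smokers carry an all-cause relative risk `RR ≥ 1` versus
never-smokers, supplied per gender and age band (defaults in the
fixtures: 1.5 / 2.8 / 2.5 / 1.8 for ages <35 / 35–54 / 55–74 / 75+,
plausible all-cause magnitudes for a Western population).  A PRRP's
"risk ratio X% of cigarettes" is interpreted as scaling the *excess*
`RR − 1` (defaults: e-cigarette 5%, THP 10%), which keeps never-users at
RR = 1.  Former users' excess decays as `(RR − 1) · 2^(−t/λ)` with
half-life `λ` (default 10 years; the published negative-exponential
estimates vary by disease and are not printed in a usable form, so the
value is exposed as configuration, not asserted).  The open-ended 20+
bin is evaluated at a representative 25 years.  Dual use takes the
maximum of the component excesses — smoking dominates — a deliberately
conservative rule given that consumption-reduction effects of dual use
are not modelled.  Former-PRRP excess uses the same decay machinery; in
joint states that carry no cigarette quit clock the representative
abstinence time defaults to 1 year (minimal decay, again conservative).
Because PRRP excess fractions are ≤ 10% of an excess that is itself
≤ 1.8, every choice about PRRP-former decay moves mortality by well
under 0.2% and none of the reported orderings depends on it.

The never-smoker mortality rate is derived once at initialization per
(gender, age): `m_never = m_all · N / Σ n_s RR_s`, so prevalence-weighted
status-specific deaths reproduce the input life table exactly at the
derivation year.  The ratio `m_never/m_all` is then held fixed, which
lets year-varying life tables shift overall mortality without
re-deriving the stratification as prevalence evolves (re-deriving each
year would make the life table endogenous to the scenario).  Life tables
published for scattered years are carried forward step-wise, not
interpolated.

## Scenario machinery

Rates are annual transition probabilities (the underlying longitudinal
estimates are at 1-year intervals), given per flow, gender, age band
(expanded by repetition, not interpolation) and year (year-specific rows
carry forward until superseded; `*` rows are the fallback).  Scenario
modifiers gate every flow touching a product to zero before its
introduction year (e-cigarette 2010, THP 2014 in the fixture scenarios),
so its stocks stay empty until then, and multiply cigarette
never→current initiation by `(1 − r)^(y − start)` from the start year on
(the "declining initiation" variants use r = 3%/year from 2020; the
decline deliberately does not touch PRRP initiation).  A pseudo-PRRP
blends two products' tables entry-wise — mean, lo95 and hi95 alike, the
simplest convention consistent with blending the means — and its risk
fraction is the same weighted average (7.5% at 50:50, 6.85% at 63:37).
Blending a table with itself is the identity at any weight, and weight 1
or 0 reproduces the corresponding sole-product scenario exactly.

Cigarette initiation hazards can be calibrated from an ever-smoking
prevalence age curve: `h(a) = (E(a+1) − E(a)) / (1 − E(a))`, floored at
0, inside a configurable window (default ages 11–30).  Simulating a
never/ever cohort with these hazards reproduces the input curve to
machine precision (tested at ≤ 1e-6 through the full engine).

Prevalence series count current users of a product among people aged
14+; dual users count toward both products by default (the published
table layouts report smoking and PRRP prevalence as separate rows
without defining exclusivity; an `exclusive` mode is provided).
Life-years lost accumulate deaths weighted by the reference remaining
life expectancy at the age of death; an alternative person-years
differencing mode is available behind `lyl_mode="person_years"`.
Comparisons are decade-sampled tables of prevalences and LYL reductions
versus a baseline scenario, with LYL in million person-years rounded to
1 decimal when written.

## Sensitivity analysis

Each run redraws every targeted rate-table row's mean from inside its
95% CI, clamped to [0, 1] — uniform by default (the least-informative
reading of "selected from within the confidence interval"); a truncated
normal with σ = CI width / 3.92 is available.  Rows are sampled
independently (no joint distribution is published).  One master seed
spawns a per-run `SeedSequence` substream; draws follow the table's
canonical entry order, so results are reproducible and independent of
scheduling.  Summaries report min/max/mean/median/SD, the 5–25th
percentiles (linear interpolation between order statistics, pinned for
comparability) and the fraction of runs in which the scenario *adds*
life-years lost.

## Synthetic fixtures

The generator emulates the shape of the public inputs this model class
consumes, not their values: a Gompertz-plus-infant-hump mortality curve
per gender (with the age-100 rate set to 1 and remaining life expectancy
computed from the same table), a survivorship-shaped pyramid with a
middle-aged bulge and 2% seeded jitter at Italy scale (59 million),
constant birth (0.8%/year) and net-migration (0.25%/year) schedules, a
logistic ever-smoking curve scaled so initial 14+ smoking prevalence
hits a target (19.7% by default, matching the anchor level reported for
Italy around 2010), a geometric quit-time distribution, and flat adult
cessation (4%/year; 8%/year for dual users, representing switching) and
relapse (5%/year base) rates.  The e-cigarette-like PRRP table uses
never-user initiation 0.6%/year (ages 11–40) and smoker→PRRP switching
2.5%/year; the THP-like table multiplies these by ¼ and 2 respectively,
the structural contrast between the published Japanese THP and US
e-cigarette transition estimates.  PRRP rows carry ±50% relative CIs.

What passing tests on these fixtures do show: structural counts,
conservation, calibration round-trips, engine–Markov equivalence,
reproducibility, and the qualitative ordering that the THP-like
structure saves more life-years than the e-cigarette-like one.  What
they do not show: any quantitative projection for a real population —
the fixtures' transition magnitudes are plausible but invented, cohort
effects and trend breaks in real prevalence data are absent, and
migration/birth schedules are flat.

## Numerical choices and problem sizes

Float64 throughout; transitions are applied from a single snapshot per
year so the engine step equals a transition-matrix product exactly
(verified against an independent matrix power to ≤ 1e-12 over 50 steps).
Tiny negative residues from float subtraction are clipped to zero.
Default analysis sizes: the full horizon is 2001–2100 (a single scenario
runs in well under a second); sensitivity analyses use 1,000 runs at a
reduced 2001–2050 horizon, which keeps a full assessment around two
minutes on one core.

## Known limitations

All-cause mortality only; no disease-specific outcomes, no economic
outcomes, and no dependence of relative risk on smoking duration or
intensity.  The dual-use maximum rule ignores compensatory consumption
changes.  Only the cigarette quit clock is tracked; PRRP quit times are
represented by a fixed default.  Simultaneous multi-product moves are
structural placeholders with zero default probability.  Migrants inherit
resident behaviour.  Outputs are projections conditional on inputs, not
forecasts.
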