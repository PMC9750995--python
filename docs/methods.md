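# Methods

## The index

The Sleep Regularity Index compares each day's minute-by-minute sleep/wake
states with the next day's. With *N* days, *M* = 1440 one-minute epochs per
day, and δ the state-agreement indicator,

SRI = −100 + 200/(M(N−1)) · Σ<sub>j=1..M</sub> Σ<sub>i=1..N−1</sub> δ(s<sub>i,j</sub>, s<sub>i+1,j</sub>).

The package computes a score per consecutive-day pair and defines window
scores (weekly, total) as unweighted means of pairwise scores:

* a pair belongs to a week only if **both** days lie in that week's window,
  so the boundary pairs (days 7→8, 14→15, 21→22) belong to no week but do
  enter the total — this keeps weeks disjoint while using all information
  in the 28-day score;
* with no exclusions, mean-of-pairwise reproduces the closed-form double
  sum exactly (verified against an independent triple-loop oracle in the
  test suite, 200 random matrices, 1e−9).

Week windows are days 1–7, 8–14, 15–21, 22–28; any tiling can be passed
explicitly.

### EXCLUDED epochs

Actigraphs are removed for showers, swimming, or malfunction; those minutes
are EXCLUDED, a third state that carries no sleep/wake information. Two
policies are implemented:

* `renormalize` (default): a column where either day of a pair is EXCLUDED
  is dropped and the pair's agreement is divided by the number of remaining
  valid columns. This is the unbiased reading — an excluded minute neither
  adds nor removes evidence of regularity — and reduces to the printed
  formula on complete data.
* `as-wake`: EXCLUDED is recoded WAKE and the denominator stays at M.
  Older device-side scripts sometimes behave this way; the flag exists so
  both conventions can be compared on the same data.

Scores are missing (NaN), never zero, when a pair or window has no valid
column at all.

### Day anchoring

Day 1 begins at the first occurrence of the day-start clock time (default
17:00, matching an evening discharge) at or before the first record;
leading un-recorded minutes of that day are EXCLUDED rather than shifting
the grid. This keeps all participants on the same clock grid while
tolerating late watch starts. Timestamps are local clock time; the 28-day
window is assumed DST-free.

## Quality control

A participant is analyzable with (a) at least 7 days containing any
non-excluded epoch (not necessarily consecutive — the weakest defensible
reading, configurable) and (b) at most 1 day carrying ≥ 6.0 h of EXCLUDED
minutes, both boundaries inclusive. Degrading data can only ever exclude a
participant (monotonicity, property-tested).

## Daily metrics

* **SOL** — minutes from rest-interval start to the first SLEEP epoch;
  **WASO** — WAKE minutes after that onset inside the interval;
  **sleep duration** — SLEEP minutes in the interval; **efficiency** —
  100 · sleep / (interval length − EXCLUDED minutes). An interval with no
  sleep at all scores SOL = length, WASO = 0, duration = 0, and is flagged.
* **Naps** count only when the day's diary reports one; an unreported quiet
  spell is not a nap. Weekly nap means divide by days (zero-nap days count),
  not by naps.
* **Light**: a minute is "bright" iff lux ≥ 250 (inclusive). Light days are
  anchored at 22:00 (device capture start), independent of the 17:00 sleep
  day; within each light day, minutes with clock time in [10:00, 22:00) are
  daytime, the complement nighttime, so day + night = 24-h total by
  construction. Missing lux is excluded from sums; an entirely unlit-
  unrecorded day is missing.
* **Alcohol**: relapse = any drink over the follow-up; heavy drinking day
  ≥ 4 drinks (F) / ≥ 5 (M), inclusive; percent days abstinent uses
  non-missing diary days as the denominator. Missing diary entries stay
  missing — an empty cell is not zero drinks, and a fully missing diary
  yields an unknown (not false) relapse status.

## Cohort statistics

Bivariate screening uses chi-square for categorical variables and
Student's t (or Wilcoxon rank-sum) for continuous ones; correlations are
Pearson with pairwise deletion. No multiple-testing correction by default
(α = 0.05 two-sided), with an optional Bonferroni flag.

The logistic stage fits nested blocks — SRI alone, then + age, then
+ subjective sleep efficiency, the blocks being directly specifiable —
reporting per-unit odds ratios with Wald 95% CIs. Complete separation is
flagged, never silently estimated; single-class outcomes, constant
predictors, and very small samples are refused with explicit messages.

The weekly-SRI model is y<sub>s</sub> = X<sub>s</sub>β + ε<sub>s</sub> per
participant with fixed effects relapse, week (categorical), nap duration,
relapse×week and nap×relapse, and block-diagonal residual covariance built
from one of three structures over the week grid: compound symmetry, AR(1),
unstructured. β is profiled out by GLS and structure parameters are
estimated by REML; the scale is profiled analytically for CS/AR(1) and the
unstructured matrix is optimized on its Cholesky factor started from the
empirical residual covariance. Since all candidates share the same fixed
effects, REML criteria are comparable: AIC (penalizing covariance
parameters) selects the structure, BIC breaks ties. Fixed effects are
reported as Wald F tests. The denominator degrees of freedom use the
residual method, N<sub>obs</sub> − rank(X), stated in the report; fancier
small-sample df corrections (Satterthwaite, between-within) are out of
scope, and under the null the week test's type-I error is calibrated to
5% ± 1.5% over 1000 replicates in the acceptance suite. The compound-
symmetry fit reproduces statsmodels' random-intercept MixedLM (REML) to
~1e−7 in the fixed effects, which serves as the independent cross-check;
with independent homoscedastic residuals the CS correlation shrinks to ~0
and the fit coincides with OLS.

## Synthetic cohort

The generator emulates a 28-day post-discharge actigraphy follow-up:

* **Schedule**: nightly bedtime = habitual time (23:30) + Gaussian jitter;
  each participant's jitter SD is 30 min scaled by a lognormal(σ = 0.95)
  factor — the population heterogeneity that spreads realized SRI. Sleep
  duration 450 ± 30 min, SOL exponential (mean 15 min), WASO 5 wake
  min/sleep-hour scattered after onset. Clock jitter is truncated at ± 6 h.
* **Naps** occur near a per-participant habitual early-afternoon time with
  per-participant Beta-distributed propensity (mean 0.4) and duration
  90 ± 45 min; a nap mechanistically delays the next bedtime by 0.4 min per
  nap minute, so heavier nappers are less regular (a pure-correlation mode
  exists behind a flag). Naps are always diary-concordant.
* **Missingness**: occasional 2-h device-off blocks (p = 0.05/day); 15% of
  participants abandon the watch before day 7; 18% accrue 2–4 days with
  ≥ 6 h excluded. Together these fail roughly a third of enrollees at QC,
  the attrition level typical of post-discharge actigraphy follow-ups.
* **Light**: per-minute lognormal lux with window-dependent location
  (awake-daytime ≈ 10% of minutes ≥ 250 lux, awake-night ≈ 2%, asleep ≈ 0),
  missing wherever the watch is off.
* **Relapse** is drawn from a logistic link on the participant's *realized*
  total SRI (intercept 2.29, slope −0.05 log-odds per SRI point), so the
  slope the statistics stage estimates is exactly the generating slope —
  the estimand and the generator coincide by construction. Diaries then
  realize the label: relapsers start drinking on a uniform day 1–18 with
  escalating weekly amounts; non-relapsers log zeros; ~3% of entries are
  missing.
* Subjective covariates (PSQI, subjective sleep efficiency) are noisy
  linear functions of realized SRI with slopes chosen to reproduce the
  reported correlation magnitudes (≈ ±0.3–0.4).

Defaults reproduce the published cohort profile this design emulates: mean
total SRI ≈ 70 (spread ≈ 9–10, somewhat tighter than the clinical 12.6),
relapse ≈ 23%, sleep ≈ 7.5 h. Everything is deterministic given
(seed, participant index) via independent seed-sequence streams.

What the generator does **not** emulate: sleep-stage architecture,
ultradian cycling, device noise or accelerometer-count scoring, seasonal or
weekday structure, and any dose–response between drinking amount and
schedule disruption (relapse feeds back into the schedule only through the
optional extra-jitter flag). Passing tests therefore demonstrate that the
pipeline recovers known structure of this class — not that the clinical
effect sizes themselves are reproduced from raw patient data, which is not
public.

## Problem sizes in the test suite

The acceptance suite runs 200 random matrices for the formula-equivalence
oracle, 1000 random days for light conservation, 200 cohorts of n = 500
(generated without the missingness machinery so the logistic estimand is
exact) for parameter recovery, and 1000 replicates each for the t-test and
mixed-model type-I calibrations — sizes chosen to put Monte-Carlo error
well inside the asserted bands while keeping the default `pytest` run in
the minutes range.

## Known limitations

* The residual-df F tests are mildly liberal in very small samples; the
  calibration band is verified at the suite's cohort sizes, not at n < 20.
* WASO/SOL defined off scored intervals approximate, but cannot exactly
  replicate, proprietary device-software scoring.
* The excluded-epoch renormalization is one defensible reading of how
  device-side scripts handle invalid minutes; the `as-wake` flag covers the
  alternative, and totals can differ by a few points between policies on
  heavily excluded records.
* Race/ethnicity recodes follow the 3-level (White / Black-African
  American / Other) and 2-level marital conventions of the emulated design.
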