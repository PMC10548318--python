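# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and the design decisions taken where the design
was genuinely open.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model

One row per meditation session: user id, timestamp, ordinal mood 1–5
(single-item "How are you today?" check-in taken before the session),
session length in minutes, content labels (practice type, worldview,
orientation, interoceptive/exteroceptive/other focus, content tag used
by the children/sleep filter), rating and play statistics, mood
attributions, and time of day.  Per-user onboarding covariates: continent
(6 levels), age (≥ 18), four reasons for meditating, six prior-experience
indicators.

## Practice periods and the forward shift

Sessions are segmented into *practice periods*: maximal runs with every
consecutive calendar-day gap ≤ `gap_days` (default 7).  A gap of exactly
7 days stays within a period ("no longer than" semantics); 8 days starts
a new one.  Gaps are measured as calendar-day differences of the
timestamp dates, not 24-hour blocks — "days between sessions" is
calendar language, and day resolution matches the days-per-week
predictor.

Within a period of *k* sessions, the forward shift yields *k − 1*
analysis rows: row *j* carries the predictors of session *j* and the
mood of session *j + 1*.  The period's first mood becomes the
`baseline_mood` covariate and contributes no outcome row.  This gives a
no-leakage guarantee (all predictor timestamps strictly precede the
outcome timestamp) that the test suite asserts directly.

## Habit predictors

* `session_count` — cumulative sessions; also provided harmonized to
  the nearest 5 (`session_count_5`), ties rounding away from zero.
* `days_since_last` — calendar days since the previous session.
* `days_per_week` — distinct meditated days in the trailing 7 days,
  inclusive of the current day.  Whether the week is a trailing window
  or a calendar week was an open choice; the trailing window is the
  default and the window length is a parameter.
* `extero_intero_ratio` — cumulative exteroceptive count divided by
  cumulative interoceptive count.  While the interoceptive count is
  zero the ratio is undefined and stored as missing; linear models keep
  such rows with a zero-filled value plus a missingness indicator
  (preserving per-variable Ns), and a complete-case mode is available.
* `n_practice_types` — running count of distinct practice types.

Children-related and sleep meditations are removed before any feature
computation (a child may have completed the session; sleep sessions
have an unverifiable effective length).  Outlier trimming uses Tukey
fences Q1 − 1.5·IQR / Q3 + 1.5·IQR with linearly interpolated
quartiles; the quartile convention is selectable.  Double application
of the trim on the data shapes used here removes nothing further; this
is a property of the convention on those shapes, asserted as a
regression test, not a theorem.

Habit levels for stratified models: days/week {1, 2, 3, 4–7}, days
since last {1, 2, 3–7} ({1, 2, 3–4, 5–7} for adherence), length {5–10,
11–20, 21–30} min, practice types {1–4, 5–8, 9–12}, ratio levels
0:1 … 9:1 (nearest integer, capped).

## Engineered outcomes

**Equanimity** is the rolling 5-session sample SD (n − 1 denominator;
the denominator was an open choice) of mood, defined once the window is
complete, sign-flipped and min–max scaled onto [1, 5].  Scaling is
fitted on the pooled corpus of defined raw SDs across users — global
scope keeps the measure comparable between users; per-user scope is
selectable.  The smallest observed SD maps to 5, the largest to 1; if
all raw SDs are equal the scale is degenerate and every value maps
to 5.

**Resilience** events open when a session's mood is ≥ 1 point (the
`drop` parameter) below the user's trailing-week mean mood.  The
reference excludes the current session (a drop should not dilute its
own reference) and is frozen when the event opens; both choices are
config-switchable since the original operationalization does not pin
them down.  A counter then counts sessions until the first with mood ≥
reference.  One event may be active at a time; deeper drops during an
open event do not reset the counter.  Events still open at end of
stream are censored and excluded from analysis tables — an unreturned
drop may simply be churn.

**Adherence** uses users with ≥ 30 sessions; features aggregate the
first 30 sessions only (dominant time of day, mean days/week and
days-since-last mapped to habit levels, mean length bin, practice-type
count bin, ratio level at session 30, baseline mood), and the label is
reaching ≥ 150 total sessions, the top-decile milestone of typical
usage distributions.

## Models

**Linear mixed model.**  Gaussian, fixed effects for the dose/habit
predictors and covariates, with users nested in their continent of use:
a random continent intercept plus per-user random intercepts.  The fit
is a profiled REML over the two variance ratios; because both random
designs are disjoint indicator blocks, V⁻¹ and log|V| follow from two
Sherman–Morrison steps in O(N) per evaluation (Nelder–Mead on the log
ratios, tolerances 1e−4/1e−6).  statsmodels `MixedLM` fits the same
structure through variance components and is retained as an alternative
engine and as the independent cross-check in the tests; it is
impractical at study scale because the per-user components become dense
dummy blocks.  Wald 95% CIs and normal p-values throughout; symmetric
Wald intervals match the reporting convention of the coefficient
tables this layout mirrors.  Non-convergence flags the result rather
than raising; rank-deficient designs raise an error naming the
dependent columns.

**Nonlinear dose-response smooths.**  Penalized cubic B-splines
(default basis dimension 10) of outcome vs session count via
statsmodels `GLMGam`, penalty chosen by GCV.  No installed package
provides penalized thin-plate bases; penalized B-splines are the
package's spline family, with basis size and penalty exposed in the
model spec.  By-factor smooths are realized as one fit per habit level
(matching per-level plotted curves); each level's session axis is first
truncated at the largest harmonized session count whose relative
frequency is ≥ `support_cutoff` (default 1%), and levels with too few
rows or too few distinct x values are dropped with a logged warning.
Smooth-term p-values are Wald tests on the spline coefficient block.
The smooths use parametric covariates without random intercepts by
default — `GLMGam` has no random effects; with user-level intercepts
absorbed into the baseline covariate the pooled curves recover injected
profiles accurately (the recovery study quantifies this).  The fitted
smooth is parameterized as a contrast against the axis origin, so
curves are compared after centring or anchoring.

**Adherence logistic regression.**  Binomial GLM with treatment-coded
factors; documented reference levels are the least-intensive habit
levels (days/week "1", days since last "1", length "5–10", types
"1–4", ratio "0:1", time of day "night").  Complete or quasi-complete
separation yields a flagged result with a diagnostic instead of a
crash.  Odds ratios and CIs are exponentiated Wald intervals.

**FDR.**  Benjamini–Hochberg step-up q-values, computed within each
model's coefficient table (one FDR family per table, matching a
single Q column per reported model table; not pooled across models).

## Synthetic generator

Latent mood for user *i*, session *j* (1-based):

```
latent = baseline_i + session_effect·(j−1) + consistency_effect·dpw_ij
         + profile(j) + N(0, noise_sd²)
mood   = 1 + #{cutpoints < latent}
```

with global cutpoints (−1.5, −0.5, 0.5, 1.5) — a standard
latent-Gaussian ordinal DGP whose expectations are computable in closed
form (`expected_mood`), which makes parameter-recovery targets exact.
Defaults: `noise_sd` 0.6 and `baseline_latent_sd` 0.3, chosen so the
marginal mood distribution is centred on "OK" with SD comparable to
observed single-item mood scales, and so the latent→ordinal derivative
is ≈ 1 near the scale centre (effects on the two scales nearly
coincide).  Baseline mean 0 puts the typical user at category 3.

Inter-session gaps are truncated-geometric on {1, …, 14} days with
success probability 0.28, putting ≈ 90% of gaps at ≤ 7 days — matching
the observation that a 7-day threshold captures about 90% of the
between-session gap distribution; the distribution is a modelling
choice exposed in the config.  Churn is an absorbing per-session
dropout with hazard `1/mean_sessions_per_user` unless set explicitly,
so uncapped session counts are geometric (verified by a chi-square
goodness-of-fit test at n = 10,000 users).  Age is normal (37.5, 12.6²)
truncated at 18; continent, reasons, experience, practice type,
worldview, orientation and focus marginals follow the categorical
schema of a large international meditation-app cohort.  All draws flow
from one root `SeedSequence` through named child streams (users,
counts, gaps, latent, content), so stages are independently
reproducible and seeded runs bit-identical.

What the generator does *not* emulate: weekly/diurnal seasonality,
mood-dependent churn or gap lengths (missingness is ignorable by
construction), content popularity dynamics, autocorrelated latent noise,
and user-specific cutpoints.  Passing recovery tests therefore show the
estimators are correct under ignorable missingness and a
homogeneous threshold model — not that real app data meet those
assumptions.  The geometric churn also yields a lighter-tailed session
distribution than real cohorts, so the synthetic adherer fraction is
smaller than practice.

## Recovery studies (sizes as run)

* Linear: 100 replicates at n = 500 users, ~15 sessions/user,
  `session_effect` 0.01; the truth is the model-scale implied slope
  from the threshold expectation (noise-free within-user OLS at
  n = 20,000), and CI coverage of it is reported.
* Adherence: 100 replicates at n = 2,000 users; log-odds +log 2 for the
  4–7 days/week level, recovery on the odds-ratio scale.
* Nonlinear: one fit at n = 1,000 users with a saturating profile
  0.4·(1 − e^−(j−1)/8); the fitted smooth is compared (centred) with
  the generator's tabulated expected-mood curve; RMSE and the fraction
  of total gain attained in the first third of the axis are reported.

## Known limitations

* Mood is treated as numeric in the gaussian models (as in the
  reporting convention the tables mirror); ordinal-response mixed
  models are out of scope.
* The GAM smooths omit random intercepts; with strong between-user
  heterogeneity and informative dropout the pooled curves could be
  biased — in the recovery setting dropout is non-informative so this
  does not arise.
* Time zones are not inferred; timestamps are taken at face value.
* The continent variance component rests on only six levels and is
  weakly identified; it is reported but should not be interpreted
  tightly.
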