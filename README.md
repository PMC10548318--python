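# medema

Longitudinal analysis of meditation-app mood check-ins (ecological
momentary assessment, EMA): feature engineering for per-session mood
streams, engineered well-being outcomes, and mixed-effects dose-response
models — validated end to end on a synthetic session-stream generator
with known ground truth.

## Who this is for

Researchers analysing app-collected repeated-measures well-being data:
each meditation session carries a single-item ordinal mood check-in
(1 = *terrible* … 5 = *great*), a timestamp, a session length, and
content labels (practice type, worldview, orientation, interoceptive vs
exteroceptive focus).  The package turns such raw streams into
model-ready tables and fits the standard longitudinal models, without
requiring access to any proprietary dataset: every stage can be
exercised and calibrated against simulated streams whose true effects
are known.

## What it computes

**Practice periods and shifted outcomes.**  A *practice period* is a
maximal run of a user's sessions with every inter-session gap ≤ 7
calendar days.  Within a period, mood scores are shifted forward — the
predictors of session *j* are paired with the mood of session *j + 1* —
and the period's first mood is removed and used as a baseline
covariate.  Gaps longer than a week therefore never link a session to a
mood it cannot plausibly have influenced.

**Habit / dose predictors.**  Cumulative session count, days meditated
per trailing week, days since the last session, the cumulative
exteroceptive:interoceptive session ratio, and the running number of
distinct practice types; box-plot (Tukey-fence) outlier trimming and
harmonization to the nearest 5 minutes / 5 sessions.

**Engineered outcomes.**

* *Equanimity*: the rolling 5-session SD of mood, sign-flipped and
  min–max rescaled onto [1, 5], so that stable mood scores high.
* *Resilience*: sessions to recovery after mood drops ≥ 1 point below
  the user's trailing-week average; open events at end of stream are
  censored and excluded.
* *Adherence*: reaching ≥ 150 total sessions, predicted from habits in
  the first 30 sessions only.

**Models.**  For a user *i* in continent *c* with shifted mood
*y\_ij*:

```
y_ij = x_ij' β + b_c + u_i + ε_ij,   b_c ~ N(0, σ_c²),  u_i ~ N(0, σ_u²)
```

a gaussian mixed model with users nested in continent (random continent
and user intercepts, profiled-REML fit with Wald 95% CIs); penalized
cubic B-spline smooths of outcome vs session count, optionally
stratified by habit level, with GCV-selected penalties; logistic
regression for adherence reporting odds ratios; Benjamini–Hochberg
q-values within each coefficient table.  A synthetic generator
(latent-Gaussian ordinal thresholding, geometric inter-session gaps,
absorbing churn) provides ground truth for parameter-recovery studies.

## Worked example

```python
import medema as m

cfg = m.SimConfig(n_users=200, mean_sessions_per_user=30,
                  session_effect=0.01, max_sessions=60, seed=42)
users, sessions, truth = m.simulate_streams(cfg)
table = m.build_feature_table(sessions, users)
spec = m.ModelSpec(outcome="outcome_mood",
                   fixed_terms=("baseline_mood", "session_count", "days_per_week"))
res = m.fit_linear_mixed(table, spec)
print(res.table.round(4).to_string(index=False))
```

prints

```
         term  estimate  ci_low  ci_high      p      q
    Intercept    2.9029  2.7701   3.0357 0.0000 0.0000
baseline_mood    0.0480  0.0128   0.0832 0.0076 0.0101
session_count    0.0096  0.0082   0.0110 0.0000 0.0000
days_per_week   -0.0198 -0.0375  -0.0020 0.0289 0.0289
```

The generator injected a dose-response slope of 0.01 latent-mood units
per session; on the observed ordinal scale the implied true slope is
`m.implied_session_slope(cfg) ≈ 0.00998`, and the fitted coefficient
0.0096 (CI 0.0082–0.0110) recovers it.  The intercept ≈ 2.9 sits at the
centre of the 5-point scale, as built into the generator; q-values are
the BH-adjusted p-values within this table.

To put a mood coefficient in plain terms: a meditator who checks in
"OK" (3) five times has a mean mood of 3.0; if one of five check-ins
shifts up to "good" (4), the mean becomes 3.2 — a change of 0.2, i.e.
one extra day of improved mood per five sessions
(`m.worked_example_check()` recomputes and asserts these numbers).

## Command line

```
medema simulate --out sim/ --seed 1 --n-users 500
medema features --in sim/ --out features.csv
medema outcomes --in sim/ --out outcomes/
medema fit      --features features.csv --out fit/
medema repro    --out run/ --seed 1       # full pipeline + manifest
```

Each pipeline run writes an `attrition.json` (row counts entering and
leaving every filter) and a `manifest.json` (config, seed, output
hashes), so a persisted config and seed reproduce every artifact.

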