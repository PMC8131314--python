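# Methods

This note documents the models and procedures `emadyn` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the known limitations of the estimator.

## Study protocol encoding

Prompts follow a signal-contingent schedule: the first prompt at
`waking_start`, then every `interval_hours` (default 3) while the time
stays ≤ `waking_end` (**inclusive end**), repeated for `n_days` (default
42). With the default waking window 08:00–22:59 this yields exactly five
prompts per day (08:00, 11:00, 14:00, 17:00, 20:00); a window ending at
23:00 would yield six — both densities are consistent with "approximately
five per day", and the default window is chosen so the nominal design is
five. A window shorter than one interval is an invalid design.

Question sets are 13 fixed items plus up to 3 personalized complaint items
and up to 5 personal factors, capped at 26 items total (so a survey stays
under a minute). Branching is a static tag (`morning_only` = first prompt
of the day, `later_only` = all others); the fixed-item labels are
placeholders for the concepts the battery covers (fatigue, restrictions,
school participation, sleep, physical/mental activity, social support,
mood, worry, relaxation, plus categorical company and location items).
Clock times are integer minutes since midnight; no time zones or DST.

## Synthetic data generator

Per subject, the continuous variables share a latent standardized lag-1
VAR: `z_t = Φ z_{t−1} + ε_t`, `ε_t ~ N(0, Σ)`, with a **stationarity
guard** (spectral radius of Φ < 1, Σ positive definite). At the first
prompt of each day the state is redrawn from the stationary distribution:
a ≥9-hour overnight gap is not one 3-hour step, so in truth no lag-1
dependence crosses a night — matching the estimator's pairing rule.

Observed values are

    VAS = baseline + scale·z + trend(t) + circadian(clock) + weekend·1[Sat/Sun] + context offset

clipped to [0, 100] (the clipped fraction is recorded; < 1% under the
defaults). Trend is a per-variable sinusoid (amplitude in VAS units,
period in days), circadian a cosine peaking at a per-variable clock time,
and the categorical context is exogenous i.i.d. across occasions with
per-level additive offsets. `innovations_for_unit_variance` sets
Σ = V − Φ V Φᵀ so the stationary covariance V has unit diagonal: generator
cross-lags are then directly on the estimator's standardized-beta scale.

Compliance: a prompt on day d is answered with probability
`p0 · daily_decay^d`, independent of the process (MCAR) by default. The
default plan (p0 = 0.52, decay = 0.993) puts the closed-form mean answer
fraction at 0.44 over a 49-day period — the low-forties regime typical of
adolescent smartphone EMA, where compliance is highest at the start and
slowly decreases. An optional MAR mode lowers the answer probability on
the logit scale when current latent fatigue is high, for sensitivity
analyses of the non-random-missingness caveat.

Default effect sizes (cross-lags 0.2–0.4, innovation correlation 0.3) are
chosen to straddle the relevance-filter threshold; no empirical
within-person effect sizes exist for this population. Everything is
deterministic under a seed at subject and cohort level (per-subject seeds
spawn from a master `SeedSequence`); cohort heterogeneity is emulated by
Gaussian jitter of Φ, rejection-resampled to stay stationary.

**What the generator does not emulate:** reaction-time/expiry windows,
survey duration, within-day context persistence (context is i.i.d.),
measurement reactivity, and platform artifacts (beyond the analyst-side
deduplication rule). Passing tests therefore show the pipeline recovers
the structure *this* generator produces; real EMA data can violate
stationarity and MCAR in ways the sensitivity hooks only sketch.

## Compliance metrics

"Measurements per participant" counts answered prompts (not items);
"per day" divides by the scheduled period by default (`per_day="used"`
divides by days with ≥1 answered prompt). Adequacy = ≥50 answered AND
≥3/day on average; it is monotone in answered prompts. Duplicate
(day, time, item) rows are dropped keeping the first before any counting.
The cohort time course is the per-study-day total of answered prompts; its
log-linear OLS slope estimates `log(daily_decay)` under geometric decay.

## Basic report

Each variable is aligned to the full prompt grid (missing = NaN; a record
at an unscheduled time is an error). The **low-pass trend** is a centered
moving average over `window_days · per_day_count` occasions (default 3
days → 15 occasions, forced odd), computed over non-missing values with
the window shrinking at the edges — chosen for transparency and exact
small-case oracles; the identity trend + residual = observed holds at
machine precision at every observed occasion. Hour-of-day and weekday
profiles are group means (weekday from `day_index` and a configurable
start weekday, default Monday); category profiles report per-level means
with n, flagging levels with n < 5 as low-support rather than testing them
— the basic report is descriptive by design.

## Dynamic-network estimator

The reference method for this kind of data is Bayesian residual dynamic
SEM; `emadyn` deliberately implements a transparent two-step frequentist
approximation:

1. **Covariate adjustment.** Subtract the low-pass trend, then estimate
   time-of-day slot means and a weekend offset jointly by least squares on
   the detrended series; residuals have mean zero by construction. Slots
   with no observations get a zero effect and a flag; a degenerate weekend
   indicator is dropped with a flag.
2. **Lag-1 model (≤3 variables).** Lag pairs are same-day consecutive
   prompts with *all* model variables observed at both occasions (listwise;
   no imputation; never across nights). Residuals are standardized by
   their within-person SD; each variable at t is regressed (OLS, with
   intercept) on all variables at t−1, requiring ≥10 pairs per predictor
   (configurable) and a design condition number < 10⁶. Coefficients are
   standardized betas; p-values are OLS t-tests.
3. **Contemporaneous edges.** (Partial) correlations of the lagged-model
   innovations: plain correlation for 2-variable models, precision-matrix
   partial correlations for 3-variable models (≥30 innovations required).
   P-values use the Fisher z transformation with the effective sample size
   reduced by the number of conditioning covariates (the lagged predictors,
   plus the partialled third variable) — standard partial-correlation
   degrees-of-freedom accounting.

Standardized estimates and p-values are invariant to positive affine
rescaling of any variable, and the adjustment is invariant to additive
constants.

**Relevance filter.** Keep edges with `p < 0.05` AND `|estimate| > 0.2`,
both strict, no multiple-testing correction across edges or models — the
filter is reported as stated, and the multiplicity caveat is documented
here rather than silently "fixed". The clinical-relevance step is a manual
keep/drop list applied last; curation can only remove edges. Both
thresholds are configurable (`RelevanceCriteria`); technical displays
sometimes use a 0.1 magnitude threshold, which is supported the same way.

**Model enumeration.** All subsets of 2–3 continuous variables containing
a focal variable (default fatigue), deterministically ordered.

## Calibration and recovery (measured by the test suite and acceptance script)

At the study scale — 42 days × 5/day, 42% of prompts missing at random
(~56 usable lag pairs) — Monte-Carlo experiments with this package show:

- the between-variable edge tests (cross-lagged + contemporaneous) reject
  at ≈6% at nominal α = 5% under a null generator;
- a standardized cross-lag of 0.4 is estimated with mean ≈0.36 (small
  attenuation from the short-window detrend, see below), RMSE ≈0.13, and
  survives the full relevance filter in ≈80% of replicates, versus ≈6–7%
  for a truly absent edge;
- the 57-subject cohort decay slope matches `log(daily_decay)` within
  Monte-Carlo error.

These problem sizes (1000 null replicates, 200 recovery replicates) keep
the full suite under a minute while bounding rate estimates to ±1–2
points.

## Known limitations

- **Self-edges are structurally distorted.** Subtracting a short-window
  local mean induces spurious negative autocorrelation of order −1/m
  (m = observed occasions per window; ≈ −0.1 to −0.2 under study
  conditions). Autoregressive self-effects therefore reject far above
  nominal (~15%) and are *not* treated as network edges: they are
  estimated, reported in the technical appendix, and excluded from the
  patient-facing network and from edge-rate calibration. Between-variable
  edges are unaffected to first order (each variable is filtered using
  only its own past and future values), which the null calibration
  confirms empirically.
- The same filtering mildly attenuates cross-lags (bias ≈ −0.04 at 0.4
  under study conditions) — acceptable against an RMSE of 0.13, and the
  price of a filter that is exactly oracle-checkable.
- Two-step estimation ignores uncertainty in the removed trend/covariate
  components, and OLS standard errors ignore the weak dependence the
  filter induces across adjacent pairs; both effects are small at these
  sample sizes (measured above) but real.
- No multiple-testing correction across the enumerated models; with many
  variables the technical appendix should be read with that in mind.
- Missingness handling is listwise; under state-dependent (MAR)
  missingness estimates can be biased — the generator's MAR mode exists
  precisely to probe this.

## Degenerate inputs and numerical choices

Empty schedules, all-missing series, unknown variables, records off the
grid, non-stationary Φ, non-PD Σ, insufficient pairs/occasions and
collinear predictors all raise typed errors naming the rule or threshold.
Ties at filter thresholds are excluded (strict inequalities). Report JSON
is byte-identical across reruns at fixed seed: metadata carries seeds, a
config hash and the package version, and a wall-clock timestamp only if
the caller supplies one.
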