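# Methods

## Nightly parameter derivation

Each night is an ordered sequence of 30-second epochs in one of five
states: WAKE, LIGHT, DEEP, REM, ABSENCE (not in bed). All derivations are
exact epoch counts times 0.5 min; nothing in the statistics path is ever
rounded to whole minutes (whole-minute rounding of TST and WASO exists only
in the display layer, `noctvar.report.display_round`, half-up).

The analysis window is the half-open epoch span from the first epoch after
the last ABSENCE preceding the first sleep-stage epoch (or epoch 0 if there
is none) to the first ABSENCE after the last sleep-stage epoch (or the end
of the recording). Within it:

* **SL_adj** — epochs from the window start to the first LIGHT/DEEP/REM
  epoch. When a pre-sleep absence exists this is latency from the end of
  that bout; otherwise from the start of the (user-initiated) recording.
  Sleep onset is the first sleep-stage epoch; no persistence rule is
  applied.
* **TST** — count of LIGHT/DEEP/REM epochs in the window.
* **WASO** — WAKE epochs strictly between the first and last sleep epochs;
  ABSENCE epochs in that span contribute nothing.
* **Final awakening** — epochs from the last sleep epoch to the window end.
* **TIB** — non-ABSENCE epochs in the window (window-scoped presence; this
  makes SE = 100·TST/TIB and the partition identity
  SL_adj + TST + WASO + FA = TIB internally consistent in absence-free
  windows and keeps pre-window lounging out of SE).

A recording with no sleep-stage epoch yields an invalid night (flagged, not
dropped; the pipeline logs the excluded count). Indexing is 0-based with
half-open windows; durations are minutes.

## The location-scale mixed model

For nightly outcome $y_{ij}$ (subject $i$, night $j$; outcomes: sleep
efficiency in percentage points, durations in minutes):

$y_{ij} = \beta_0 + \beta_g g_i + \beta_a(a_i-\bar a) + \beta_s s_i + b_i + e_{ij}$,
with $b_i \sim N(0,\sigma_b^2)$ and $e_{ij} \sim N(0,\sigma_w^2(g_i))$.

Because $b_i$ enters linearly, each subject's nights are jointly normal
with covariance $\sigma_w^2 I + \sigma_b^2 J$; the likelihood is evaluated
in closed form in $O(n_i)$ per subject via the rank-one
(Sherman–Morrison) structure rather than by numerical integration. The
test suite cross-checks this closed form against a 64-node adaptive
Gauss–Hermite quadrature written from the integral definition (agreement
to 1e-8) and against `nlme::lme` with `varIdent` group weights under ML.

Numerical choices:

* Variance parameters are optimised on the log scale. The mean
  coefficients are profiled out in closed form (GLS), so the optimiser
  works on three parameters (log σ_b, log σ_w per group): L-BFGS-B followed
  by Newton polishing with a finite-difference Hessian of the analytic
  gradient. Near the optimum the likelihood is flat to machine precision,
  so Newton steps are also accepted on gradient-norm decrease.
* `converged` requires the full 7-parameter gradient max-norm below 1e-6
  (the profiled mean gradient is exactly zero at the GLS solution).
* σ_b has a log-scale floor at −10; a fit pinned there reports σ_b = 0
  (boundary solution), with the floor's inward gradient excluded from the
  convergence check.
* The covariance of the estimates is the inverse observed information
  (central-difference Hessian of the analytic gradient); natural-scale SEs
  for the σ parameters follow by the delta method. A singular Hessian is
  reported explicitly and blocks `converged`.
* Starting values: OLS for β, pooled within-subject moment estimates for
  σ_w(g), a between-minus-within moment estimate for σ_b.
* Age is centred at the mean age of the distinct subjects; predictions
  decentre it. Degenerate designs (a constant sex column, fewer than two
  subjects per group with two or more nights) are rejected at fit time.

Planned contrasts: the mean contrast tests $\beta_g$; the variability
contrast tests $\sigma_w(\text{ins})-\sigma_w(\text{ctl})$ with the SE
delta-propagated from the log-scale covariance. Both report
$F=(\hat\theta/\mathrm{SE})^2$ on $(1,\mathrm{ddf})$ and t-based 95% CIs.
The default denominator df is `n_subjects − 5` (112 subjects → 107, the
design's subject count minus the four mean coefficients and one scale
contrast); `n_subjects − rank(mean design)` is available as an alternative.
Each outcome is fitted independently with no multiplicity adjustment
(planned-contrast framing). The model is fitted to nightly values; weekly
per-subject means and SDs (`weekly_summaries`, sample SD with n−1, null for
weeks with fewer than two observed nights) are descriptive output only.
Fitting uses exactly the observed valid nights — no imputation.

## The synthetic cohort generator

The generator emulates the study conditions: 83 insomnia / 29 control
subjects, 56 nights; ages truncated-normal on 18–65 with group means 38.3
(SD 12.0) and 29.7 (SD 8.8) years; female proportions 0.699 / 0.724;
weekly adherence declining from ~0.82 (peak 0.838 in week 3) to 0.632 for
the insomnia group and from 0.808 to 0.695 for controls, interpolated
linearly between the anchor weeks so the 8-week averages are 0.759 / 0.719.
Nights are dropped independently with their week's probability (MCAR),
matching an analysis that performs no imputation.

**Primitives and derived outcomes.** A night has four free components —
SL, WASO, final awakening and TST — from which TIB and SE follow
algebraically. The generator therefore samples the four primitives as
group mean + subject intercept + night noise and *calibrates* the two free
TST parameters so the derived sleep-efficiency contrasts hit their
configured values exactly: the TST group-mean difference is solved so
E[SE] differs by the configured −5.34 points, and the TST within-subject
SD so the within-subject SD of SE differs by 1.77 points. Both solves use
tensor-product Gauss–Hermite integration of the nonlinear SE transform
(E[SE] and E_b[Var(SE|b)]), alternated to their fixed point. The solved
values (TST difference ≈ +8 min, TST night-SD ≈ 62 min) are consistent
with group TST/TIB differences that the study design treats as
non-significant rather than zero.

**Truncation and quantisation.** Night values are non-negative and live on
the 0.5-minute epoch grid. Sampling uses exact truncated-normal draws
conditional on the subject intercept, then rounds to the grid. Because
truncation and rounding would otherwise shift the realized moments off
their targets, the raw normal parameters are obtained by inverting the
truncated-normal moment map (averaged over the intercept distribution,
with Sheppard's correction for grid variance), so the realized night
values carry exactly the configured group means and within-subject SDs.
Analytic truncation mass is ≤0.4% per outcome and group under the
defaults; a warning is emitted above 1% since heavier truncation biases
recovery.

**Default anchors.** Grand means: TIB 459 min (7.65 h), TST 395.4 min
(6.59 h), SL 29.5 min, WASO 25.7 min, final awakening implied (8.4 min).
Group differences (insomnia − control): SL +10.15, WASO +18.45 min, SE
−5.34 points. Within-subject SDs: control anchors SL 1.0, WASO 2.0, FA
2.0 min with differences +8.80, +8.60, 0; subject-intercept SDs SL 4,
WASO 4, FA 2, TST 25 min. Grand anchors split into group means as
control = m − d·w_ins, insomnia = control + d (w_ins = 83/112), which
preserves both the grand mean and the difference. The control-group SD
anchors are compressed relative to real actigraphy because the five
outcomes share only four degrees of freedom: with the configured SD
*differences* and the ~64-minute grand non-sleep budget, larger control
anchors would force double-digit truncation mass and bias every recovery
target. Consequently the control group's implied SE night-to-night SD
(~1.8 points) is lower than typically observed in good sleepers; the
insomnia-minus-control differences, which are the estimands, are exact.

**Epoch realisation.** Each night is rendered as: an optional pre-sleep
ABSENCE bout (probability 0.5, 2–20 epochs, exercising both SL_adj
branches), SL wake epochs, a sleep span with stages drawn at proportions
0.55/0.20/0.25 (light/deep/REM) and the WASO wake epochs distributed over
1–4 bouts strictly interior to the sleep span, then the final-awakening
wake epochs. Derivation inverts realisation exactly
(`derive_night(realize_epochs(t)) = t`, property-tested on 1,000 random
target tuples), so epoch-level and night-level simulation paths agree
identically.

**What the generator does not emulate.** Realistic ultradian stage
architecture, circadian clock time, informative missingness, skewed
(e.g. lognormal) night distributions, covariate effects on sleep (age and
sex coefficients are zero in truth; the model still estimates them), and
correlation between the primitive components. Passing recovery tests
therefore demonstrates that the estimation machinery is correct under the
model's own assumptions plus truncation/quantisation — not that the model
is robust to real-data skewness or informative dropout.

## Known limitations

* For the *derived* sleep-efficiency outcome, the per-subject within-SD
  varies with the subject's intercepts (the SE transform is nonlinear), so
  a single cohort's realized SD contrast fluctuates around the configured
  1.77 by roughly 1.4× the model's reported SE. The model-based SE is
  correct under the model's homoscedastic-scale assumption and matches the
  pooled empirical estimator; the extra spread is a generator-level
  property documented here rather than absorbed into the SE.
* The scale model has no random effect (no subject-specific within-SD);
  extending it to a full location-scale model with random scale is out of
  scope.
* Estimation is ML, not REML; variance estimates carry the usual small
  downward ML bias, negligible at 112 subjects × ~42 observed nights.

## Problem sizes used in the checks

Recovery checks run the full study geometry (83/29 subjects × 56 nights,
epoch-level, ~4,700 observed nights per cohort) over 25 replicate cohorts,
plus one fixed default-seed cohort for the single-cohort check. The
type-I-error study of the variability contrast uses 1,000 null cohorts at
a reduced 10+10 subjects × 10 nights so the whole suite stays fast; the
likelihood oracle comparisons use 5-subject instances where quadrature is
sharp.
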