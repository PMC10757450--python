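# Methods

This note documents the generative model, the estimators, and the
statistical machinery, together with the design choices made where the
underlying procedures are conventionally under-specified.

## The race-model observer

Each participant × session is an independent horse-race observer.

**Go process.** Finishing times are ex-Gaussian, T ~ N(μ, σ²) +
Exp(τ).  The ex-Gaussian is the standard right-skewed RT model and
gives the 800/900 ms censoring rules realistic tail mass.  Participant
level: the *mean* finishing time (μ + τ) is drawn from the
group × treatment preset (mean, between-participant SD); the
trial-level shape parameters are global generator settings
(no-stop context: σ = 60 ms, τ = 90 ms; go-only context: σ = 40 ms,
τ = 60 ms).  Only between-participant SDs are published for this kind
of design, so within-participant dispersion is a free parameter chosen
to give realistic trial-level spread (~110 ms SD) and overtime rates.

**Stop process.** A participant-level constant `ssrt_true`, drawn from
the preset SSRT mean/SD.  A constant latency makes recovery targets
well-defined: the integration estimator should return it exactly in
the large-sample limit.  On a stop trial the response is emitted iff
T_go < SSD + ssrt_true (stop failure, RT = T_go recorded), otherwise
the stop wins (no RT).

**Staircase.** SSD starts at 119.7 ms (9 refresh quanta of 13.3 ms)
and moves ±39.9 ms (3 quanta) after each stop trial — up after a
successful stop, down after a failure — clamped at 0 ms and continuous
across blocks (the block boundary is not a psychological reset and no
reset is specified by the procedure).  All SSDs therefore stay on the
refresh grid.  Stop trials are exactly one third of every block,
placed by uniform random permutation.

**Movement times.** Normal with participant-level means per task
context and trial-level SD 60 ms.  The go-only MT mean sits above the
no-stop MT mean (preparation during strategic slowing shortens
no-stop movements).

**Context-effect structure.** One latent motor-speed effect per
measure family (RT, MT, stop latency) is shared across the two task
contexts, so slow participants are slow everywhere; the go-only means
additionally receive an idiosyncratic component (default SD 30 ms,
carved out of the preset between-participant SD so marginal cell SDs
are preserved) that makes the *size* of each participant's context
effect individual.  Without it every participant in a strong-delta
cell is classified "context" and the frequency tables degenerate.

**ON/OFF correlation.** For patients, the latent effects of the OFF
and ON sessions are bivariate standard normal with ρ = 0.7 (a
within-subject design implies strongly positive correlation; ρ = 1
makes the sessions share one participant profile, ρ = 0 makes them
independent).

**Lapses and censoring.** Go-type trials lapse i.i.d. into
`target_miss` or `hold_violation` (half/half) at a rate calibrated so
that observed accuracy matches the preset after accounting for the
analytic probability of >900 ms aborts.  Responses in (800, 900] ms
are `overtime_reaching` — kept in all RT analyses, counted as correct
for accuracy by default (they land on the target; a config flag flips
them to errors).  Responses beyond 900 ms are aborted with no RT and
count as errors.

**Determinism.** All RNG streams derive from
(seed, group-index, participant-index, session-index) seed sequences;
identical configs produce byte-identical trial tables.

## Preprocessing

RTs outside mean ± 3 SD of their participant × session × task ×
trial-type cell are discarded in a single pass (mean and sample SD
computed on the untrimmed cell).  Per-participant scoping prevents
group-level leakage; single-pass (non-iterative) trimming is the
conventional reading of a ±3 SD rule.  Cells with fewer than two RTs
are left untouched with a warning.  MTs are not trimmed.

## Reactive inhibition

`estimate_ssrt_integration` follows the consensus variant of the
integration method: no-stop omissions (>900 ms aborts) are replaced by
the maximum observed RT, the augmented distribution is sorted, the RT
at rank ⌈p_failure · N⌉ is taken, and the mean SSD over *all* stop
trials (tracking-method convention) is subtracted.  The estimate is
undefined at p_failure ∈ {0, 1}.  Sessions are flagged "reliable" at
≥50 stop trials.

Race-model checks per session: independence (mean stop-failure RT <
mean no-stop RT — failed stops are the fast tail of the go
distribution, so a violation signals dependence between the
processes) and staircase health (|p_failure − 0.5| ≤ 0.1).  Failing
sessions are flagged, never auto-dropped.

Known small-sample bias: the staircase starts 3–4 steps below its
equilibrium, so early SSDs are low and the mean SSD slightly
underestimates the equilibrium value; at 160 stop trials this leaves
the group-mean SSRT a few ms below the generative value (within the
±10 ms recovery tolerance the tests enforce).  A separate edge case:
an observer whose go process is extremely fast relative to the preset
(≈2 SD tail) can pin the staircase at the 0 ms floor and hold the
failure rate above 50%; this is a property of that individual, not of
the tracking rule, which is why the staircase-tracking check uses the
preset-mean observer.

## Proactive inhibition

Three read-outs of the context effect (no-stop vs go-only):

1. **Cell means** of RT and MT per participant × session over correct
   and overtime response trials, feeding the split-plot ANOVAs.
2. **Population cumulative distributions**: equal-weight averages of
   per-participant empirical CDFs (each participant contributes
   1/n regardless of trial count).  Directionality is tested with a
   *dual one-tailed* KS pair per measure — one test's null coincides
   with the context-effect prediction, the other opposes it.  Both
   significant = the curves intersect = no effect for that measure;
   only the predicted direction significant = effect.  The overall
   verdict is "context" iff RT shifts up and MT shifts down with no
   intersection.  The averaged curves are used for display and
   direction; p-values need a sample size, so the tests run on the
   pooled trial-level samples.  Pooling clustered trials overstates
   the effective n when participants differ in their true deltas —
   a deviation of unknown direction from curve-level inference,
   accepted and documented here.
3. **Individual classification**: per participant, "context" iff
   no-stop RTs are stochastically greater AND no-stop MTs smaller
   (and no significant MT shift the other way); "inverse_context" iff
   the MTs shift significantly in the opposite direction only;
   "no_context" otherwise.  A failed RT test alone yields no_context
   rather than a fourth category.  α = 0.05, uncorrected — the
   classification is descriptive, not inferential.

**Exact KS p-values.** Two-sample KS tests use integer path-counting:
conditional on the pooled sample, label assignments are equally
likely, the statistic is evaluated only at distinct-value boundaries
(which handles ties correctly), and the exceedance count is exact in
integer arithmetic.  Exact mode is used when n·m ≤ 10⁴ (participant-
level tests), the classical asymptotics beyond (Kolmogorov
distribution two-sided, exp(−2d²·n_eff) one-sided).  `alternative`
is value-based: "greater" means x is stochastically greater than y.

## Statistics engine

**Split-plot ANOVA** (`mixed_anova`): one between factor, up to two
within factors, one observation per subject × within cell.  Classical
univariate strata: the group effect is tested against subject-within-
group; each within effect and its group interaction against the
corresponding factor × subject stratum.  Group sizes may differ (the
within structure stays proportional so the sums of squares remain
orthogonal); incomplete subjects raise.  Effect size is partial η² =
SS_effect / (SS_effect + SS_error-of-stratum).  Sphericity is trivial
for 2-level within factors (the designs used here); ≥3-level within
corrections are out of scope.  The decomposition is verified in the
tests against an independent projection-matrix oracle and against
values from R's `aov` with `Error()` strata.

**Contrasts** (`posthoc_pairwise`): any difference of two unweighted
marginal means on the group × within-cell grid.  The standard error
combines stratum mean squares through the orthogonal within-subject
projections, so purely between contrasts use the subject stratum,
purely within contrasts use the factor × subject stratum, and mixed
cell contrasts blend the two.  Degrees of freedom are those of the
contributing stratum, and the smallest such df when several contribute
(in the target design every stratum has df 57, which matches the
convention of reporting t(57) throughout).  Bonferroni correction
over the named family; plain 95% CIs from the same SE/df.  Cohen's d:
pooled-SD form for between contrasts, averaged-SD form for paired
contrasts (the within-d variant that divides by the SD of differences
needs the ON/OFF correlation and is deliberately not used).

**Bayes factors.** t-contrast BFs are JZS (Cauchy prior on effect
size, r-scale 0.707) computed by numerical integration over the
variance-ratio mixture and cross-checked against pingouin in the
tests.  Contingency tables use the independent-multinomial
Gunel–Dickey BF with Dirichlet concentration a = 1: alternative —
one Dirichlet per row; null — shared column probabilities with prior
concentrations equal to the column sums of the per-row priors; both
marginals are closed-form by conjugacy, verified against a numerical-
integration oracle.

**χ² family.** Homogeneity: Pearson χ² with adjusted standardized
residuals (O−E)/√(E(1−p_row)(1−p_col)); residual post hocs are
two-sided normal p-values Bonferroni-corrected over the number of
groups.  Group vs control 2×2 comparisons use the N−1 correction
(χ² × (N−1)/N), which keeps the test calibrated at two-group counts.

**Calibration.** The test suite verifies that every omnibus test
(group, treatment, interaction F; homogeneity χ²; N−1 χ²) rejects
null-simulated data at a rate inside [0.03, 0.07] at α = 0.05 over
1500 replicates.

## Problem sizes used in tests and the reproduction script

The packaged checks use the study-scale design: 3 patient groups × 20
participants × 2 sessions plus 30 controls, 480 SST trials (160 stop)
and 100 go-only trials per session.  The SSRT-recovery check averages
three 30-participant control cohorts; the severity-ordering check uses
20 replicate patient cohorts; staircase tracking uses 480 stop trials
of the preset-mean observer.  These sizes make every stochastic check
comfortably stable under its stated tolerance.

## What the generator does and does not emulate

It reproduces the design's generative skeleton: group × treatment
behavioural levels, race independence by construction, staircase SSD
dynamics, proactive slowing with MT shortening, censoring and lapse
rates, and within-participant ON/OFF correlation.  It does **not**
emulate learning or fatigue across blocks, post-error slowing or any
sequential dependence beyond the staircase, trigger failures or
context-dependent stop-latency variability, tremor/artifact
contamination, or visuomotor geometry.  Passing tests therefore
demonstrate that the estimators and statistics recover the truth of
*this* model family at study-sized n — not that real patient data are
free of the above complications.

## Other limitations

- The integration estimator inherits the known small-sample biases of
  staircase designs (see above); parametric or Bayesian SSRT models
  and trigger-failure modelling are out of scope.
- The population-level KS verdicts use pooled trial-level samples
  (clustered observations); with strongly heterogeneous participants
  the effective sample size is overstated.
- Balanced-complete within structure is required; missing-session
  designs need mixed models, which this engine intentionally does not
  implement.
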