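# Methods

## The statistical model

All analyses rest on a Gaussian linear mixed model with two nested random
intercepts. For an outcome (regional brain volume in mL, or a clinical
score) observed for participant *i* in center *c* at time *t* years from
baseline:

    y_cit = x_cit' β + u_c + u_i(c) + ε_cit,
    u_c ~ N(0, σ²_center),  u_i(c) ~ N(0, σ²_subject),  ε_cit ~ N(0, σ²_resid)

Fixed effects for volume models are intercept, time, age at baseline, sex
(0 female / 1 male), total intracranial volume (TIV, liters), group
(HC / PreHD / HD, indicator contrasts against HC), a time×age interaction,
and — when a study has several scanners — scanner indicator contrasts
against the first level. Random slopes are deliberately out of scope: the
random structure is exactly the two nested intercepts.

### REML estimation

The residual variance is profiled out and the two variance *ratios*
γ_c = σ²_center/σ²_resid, γ_p = σ²_subject/σ²_resid are optimized on the
log scale. Because the covariance of each center block is
I + γ_p Z_p Z_p' + γ_c 1 1', its inverse and determinant follow from two
nested Sherman–Morrison steps, so one evaluation of the profiled REML
criterion costs a few small dense products; the gradient of the criterion
is also closed-form (trace and quadratic-form terms in the same block
quantities). Optimization is L-BFGS-B with analytic gradients from a
single interior start; if a ratio is driven to the box edge the
corresponding one-ratio profile and the OLS sub-model are optimized
exactly and the best criterion value wins, so boundary estimates are
reported as exact zeros rather than tiny positives. Non-finite optima
trigger two random restarts. Convergence is declared at a relative
criterion change below 1e-8 (L-BFGS-B `ftol` 1e-13, `gtol` 1e-8; the
one-dimensional profiles are polished to `xatol` 1e-10 when the
gradient-based pass fails). With fewer than two centers the center
variance is structurally inestimable and is fixed at zero with a logged
warning.

Wald inference uses t statistics. Two degrees-of-freedom conventions are
available: residual df (n_obs − rank X), the default for cohort fits and
interaction tests — simple and conservative at these sample sizes — and a
between-within partition used by the trial treatment test, where columns
varying within participants (time, arm×time) receive
n_obs − n_participants − q_within df and the rest n_participants −
q_between. The between-within choice makes the arm×time test in a
two-visit, zero-center-variance trial *exactly* the two-sample t test on
per-participant slopes whenever the subject-variance estimate is interior
(the REML criterion then separates into orthogonal between/within strata);
this identity is verified to ~1e-7 in the tests and anchors the simulated
power to the closed-form noncentral-t benchmark.

### Covariate adjustment

The adjusted baseline volume of a participant is the observed baseline
minus the fitted nuisance contributions — age, sex, TIV, scanner, voxel
size and time×age — evaluated relative to the sample means of those
covariates over baseline rows. Centering at sample means (the reference
covariate values are otherwise arbitrary) keeps adjusted volumes on the
observed scale and comparable across groups; the group contribution is
retained. The per-participant residual is observed minus the full
conditional fit including predicted (BLUP) center and participant
intercepts.

## Standardized effect sizes

For each region and study, t = (mean_HC − mean_PreHD) / sd(PreHD
residuals) on adjusted baselines, so atrophied regions are positive and
enlarging compartments (CSF) negative. The denominator's residuals are
conditional (random effects subtracted) by default; a `marginal` switch
uses the SD of the PreHD adjusted baselines instead, since the source
convention is ambiguous. Confidence intervals are percentile bootstrap
over participants, resampled with replacement *stratified by group* so
group sizes are preserved (2,000 resamples, 95% by default); degenerate
resamples with zero PreHD spread are redrawn and counted. Percentile
intervals are the simplest method consistent with a plain bootstrap;
coverage of a known standardized effect 0.5 at n = 100/group is ~95% in
the built-in check. Cross-study summaries weight each study by its
HC + PreHD participant count; the selection rule keeps regions with
weighted |t| strictly above 0.5 (Cohen's "medium" anchor), ordered by
descending magnitude with lexicographic tie-break; effect maps are
normalized by the maximum |t| across all studies and regions. Between-study
effect-size differences are tested by an independent two-study bootstrap of
t_a − t_b (two-sided tail probability), Bonferroni-adjusted by the caller.

## Trial power simulation

A trial has Nc centers × Nppc participants, three visits at 0/1/2 years by
default, and 1:1 within-center randomized allocation. Outcomes are drawn
from the mixed model above with hyperparameters taken from a fitted
longitudinal model (intercept → baseline mean, time coefficient → placebo
slope, variance components copied). Treatment slows the slope by a
center-specific fraction δ_c ~ N(δ, τ²) truncated to [0, 1]; δ is the
nominal treatment effect (0.2 = 20% slowing, the standard
disease-modification reading of a fractional effect) and τ the
between-center SD of that fraction, default 0.25·δ — the source states
only that the between-center treatment-effect variance is nonzero, so τ is
exposed as configuration. Each replicate is refitted with fixed terms
{intercept, time, arm, arm×time} and the nested random intercepts; power
is the fraction of converged replicates with two-sided arm×time p < α =
0.05 (non-converged fits are excluded from the denominator and the
fraction reported; above 10% the estimate is flagged). Default n_sim is
1,000 per design point (Monte-Carlo SE ≈ 1.3 points near power 0.8).

Design grids follow the published geometry: Nc ∈ {6…100} step 2 at
Nppc = 20, and Nppc ∈ {30…500} step 10 at Nc = 4, truncated at 2,000 total
participants. Replicate r of grid point g draws from a generator keyed by
(seed, g, r) — *not* by δ or τ — so curves at different treatment effects
share common random numbers and are pointwise ordered up to per-trial
flips. The threshold search runs on an isotonic regression of raw power on
total n (raw values are always retained); the smallest grid total with
smoothed power strictly above 0.8 is reported, or none if the cap is
reached first.

## The synthetic cohort generator

The generator emulates the structure of three multicenter HD observational
studies: 20 centers/265 participants, 4/294, and 1/65, with group totals,
age, sex ratio, TIV and CAG distributions per group following the
published baseline demographics tables (HC CAG is drawn truncated below
36). Group totals are dealt to centers round-robin. Volumes are built as
baseline mean + covariate effects (age, sex, TIV, time×age referenced at
age 45, sex 0.5, TIV 1.39 L) + group baseline offset + group atrophy slope
× time + per-scanner offset + center, participant and visit-level Gaussian
noise. Group offsets and slopes are free parameters rather than
CAG-derived — the generative link between CAG burden and atrophy rate is
not specified by the source, and free parameters keep the model
identifiable. Scanner offsets are drawn once per (scanner, outcome) from
N(0, (0.5·σ_resid)²), constant over time, making scanner a genuine fixed
effect. Clinical markers (TMS/SDMT/SWRT analogues) use the same nested
error structure with slope-to-residual-SD ratios an order of magnitude
below the imaging regions', reproducing the qualitative fact that they are
weak progression markers. The default region set is a small named subset —
caudate, pallidum, putamen, insula white matter, nonventricular CSF, and
two low-signal distractors — not the full 83-region atlas, for test speed;
offsets are scaled so striatal effect sizes land in the 0.9–1.5 range and
distractors below 0.5.

What the generator does *not* emulate: dropout and missing visits
(complete 3-visit cases only, matching the source's inclusion rule),
CAG-dependent progression, non-Gaussian noise, segmentation failures or QC
exclusions, and scanner drift over time. Passing tests therefore
demonstrate correctness of the estimation and simulation machinery under
the assumed hierarchical Gaussian model, not robustness to those
real-data complications.

## Numerical and reproducibility choices

* Every stochastic stage draws from a PCG64 generator keyed by the master
  seed plus a stable tag path (stage, region, grid point, replicate), so
  adding a region or grid point never perturbs other results.
* Pipeline CSV/JSON floats are rounded to 6 significant digits so repeated
  runs are byte-identical.
* Rank-deficient fixed-effect designs raise an error naming the collinear
  columns (QR with pivoting); participants lacking a complete visit set
  are excluded at load time with a log entry; a scanner change within a
  participant is an error.
* Degenerate inputs: zero-variance bootstrap data yields a zero-width
  interval at the point estimate; an all-zero effect map cannot be
  normalized and raises; perfect model fits (rss ≈ 0) short-circuit the
  criterion gradient.

## Problem sizes used in the checked examples

The test suite and acceptance script scale the study conditions to sizes
chosen for precision per unit time: REML oracle checks on 10×10 balanced
layouts; parameter recovery on 20 centers × 30 participants × 3 visits;
effect-size recovery with 200 estimator replications and 500 bootstrap
coverage replications at 500 resamples; test size at 1,000 simulated null
trials; the analytic power comparison at 2,000 replicates per effect size;
power curves on 3–8-point grids at 100–300 replicates; the
many-vs-few-centers comparison at 1,500 replicates per design. The
many-small-centers advantage under treatment-effect heterogeneity is
demonstrated with synthetic hyperparameters in the regime where the
center-level term (τ·|slope|/√Nc) is comparable to the residual slope
noise — with τ = 0.25·δ the effect is otherwise swamped for
noisy outcomes, since the center-heterogeneity share of the estimator
variance scales as (τ/δ)²·ncp²/Nc.

## Known limitations

* Degrees-of-freedom methods are the simple residual and between-within
  conventions; no Satterthwaite or Kenward–Roger correction, so Wald p
  values in very small or very unbalanced designs are approximate.
* Variance-component uncertainty is not propagated into power
  hyperparameters; power curves condition on the fitted values.
* The bootstrap difference test between studies ignores the (shared)
  model-fitting step; it resamples adjusted values, not refits.
* Composite endpoints combining regions, cost trade-offs between centers
  and participants, and anatomical rendering are out of scope.
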