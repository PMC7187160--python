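# cohortpower

Multicenter volumetric biomarkers for neurodegenerative trials: nested
mixed-effects modelling, cross-study standardized effect sizes, and
simulation-based statistical power for multicenter trial designs.

The package is aimed at biostatisticians planning disease-modification
trials from multicenter observational imaging cohorts — the motivating
setting is Huntington disease, where regional brain volumes (caudate,
pallidum, putamen, insula white matter, nonventricular CSF) atrophy years
before motor diagnosis and are candidate trial endpoints alongside noisy
clinical scales (TMS, SDMT, SWRT).

## The model

Regional volume `y_cit` of participant *i* in center *c* at visit time *t*
(years from baseline) follows a linear mixed model with nested random
intercepts:

```
y_cit = β₀ + β_t·t + β_age·age_i + β_sex·sex_i + β_TIV·TIV_i
        + β_g·group_i + β_ta·(t·age_i) [+ scanner] + u_c + u_i(c) + ε_cit

u_c ~ N(0, σ²_center),  u_i(c) ~ N(0, σ²_subject),  ε ~ N(0, σ²_resid)
```

fitted by REML (variance ratios profiled on the log scale, boundary
estimates reported as exact zeros). On top of this the package computes:

* **Adjusted baseline volumes** — the observed baseline minus fitted
  nuisance contributions (age, sex, TIV, scanner, time×age) centered at
  sample means, retaining the group contribution.
* **Standardized effect sizes** `t = (mean_HC − mean_PreHD) / sd_resid(PreHD)`
  per region and study, with stratified participant-level percentile
  bootstrap CIs (2,000 resamples), participant-weighted cross-study means,
  a strict `|t| > 0.5` selection rule, and max-normalized effect maps.
* **Trial power by simulation** — trials with participants nested in
  centers, a treatment that slows the placebo atrophy slope by a
  center-specific fraction `δ_c ~ N(δ, τ²)` truncated to [0, 1], refitted
  per replicate with the nested mixed model; the treatment effect is the
  two-sided Wald t test on the arm×time coefficient. Power curves over
  design grids (varying centers at fixed per-center size, or vice versa,
  capped at 2,000 participants) are isotonic-smoothed to locate the
  smallest total n with power > 80%.
* **A synthetic cohort generator** mirroring three multicenter HD studies
  (20/4/1 centers, 265/294/65 participants, HC/PreHD/HD groups, three
  annual visits, demographic distributions, scanner offsets) that drives
  the tests and examples, plus the small derived-variable utilities
  (disease burden score `age × (CAG − 35.5)`, TIV as CSF + cortical GM +
  deep GM + WM, bilateral region combination).

## Worked example

```python
import cohortpower as cp

cohort = cp.generate_cohort(cp.default_cohort_config(), seed=1)

spec = cp.ModelSpec(response="caudate",
                    fixed_terms=("intercept", "time", "age", "sex", "tiv",
                                 "group", "time:age", "scanner"))
track = cohort.data[cohort.data["study"] == "TRACK"]
fit = cp.fit_lmm(track, spec)
adj = cp.adjust_baseline(fit, track, spec)
stat = cp.EffectSizeStatistic()
print(round(stat(adj), 3))                      # 1.476
print(round(float(fit.params["time"]), 4))      # -0.0651

hyper = cp.extract_hyperparameters(fit, treated_fraction_sd=0.1)
design = cp.TrialDesign(n_centers=20, n_per_center=20, delta=0.4, n_sim=300)
est = cp.estimate_power(design, hyper, seed=1)
print(round(est.power, 3))                      # 0.233
```

The first number is the standardized HC-vs-PreHD effect size of the
adjusted baseline caudate volume in the TRACK-like study (large, as
configured for striatal regions); the second is the fitted annual caudate
slope in mL/year, averaged over this cohort's groups; the third is the
Monte-Carlo power of a 400-participant, 20-center, 3-visit trial to detect
a 40% slowing of that slope at α = 0.05 — well below the 80% convention,
because the fitted cohort mixes healthy controls and premanifest carriers,
diluting the average progression rate a trial would act on (the pipeline
proper fits gene-carriers only for this step).

A command-line interface mirrors the library:

```sh
cohortpower generate --seed 1 --out cohort.csv
cohortpower fit cohort.csv --region caudate --study TRACK
cohortpower effects cohort.csv --region caudate --out effects.csv
cohortpower run --config run.yaml      # full generate→fit→effects→power bundle
```

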