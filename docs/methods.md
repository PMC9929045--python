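# Methods

## The composite severity model

`relsev` scores multivariate welfare deviations against a reference
experiment. The model has three layers:

1. **Standardization** (`data_model`). Continuous readouts (body weight,
   burrowing activity) are rescaled per animal to 100% at the baseline day
   (default −1, the day before the intervention; day 0 is the first
   post-intervention day). Ordinal readouts (nest quality 1–6, distress
   score) are *not* standardized: a ratio to a zero-valued healthy baseline
   is undefined, so they stay on their native scale. Standardization is
   idempotent and unit-free, which the test suite checks as properties.

2. **Reference scaling** (`relsa`). A reference cohort supplies one
   maximal adverse deviation δ_ref_v per variable. Two aggregation modes
   exist because the field does not fix one:
   * `cohort_median_extreme` (default) — the extreme of the day-wise cohort
     *median* trajectory; robust to single outlier animals;
   * `per_animal_extreme` — the worst single animal's worst day; a
     sensitivity-analysis alternative that yields larger denominators and
     hence smaller scores.
   A variable with zero reference deviation would make the scale degenerate
   and is rejected rather than silently dropped.

3. **Combination**. Per day, each available variable contributes a weight
   w_v = δ_v/δ_ref_v and the composite is the root mean square of the
   weights. RMS is this package's defining convention: it rewards large
   deviations over diffuse noise, returns exactly 1 when every measured
   variable sits at its reference extreme (for any subset of variables),
   and admits values above 1 for animals worse than the reference. The
   combiner is pluggable (`relsa_timeseries(combiner=...)`) for sensitivity
   analyses. Equivalence with other published implementations of
   reference-scaled composites is not claimed; the invariants above are the
   contract, and the tests enforce them (monotonicity, permutation
   invariance, scale-freeness, RELSA ≤ max w ≤ RELSA·√n).

Adverse direction is down for body weight, burrowing and nesting, up for
the distress score. Beneficial deviations clip to zero — improvement on one
readout must not mask distress on another. Missing measurements shrink the
per-day variable count n(t) instead of being imputed: absence of a
measurement is not absence of distress. The ordinal baseline defaults to the
scale's healthy bound (distress 0, nesting 6); an observed-baseline variant
is available through the explicit baseline argument of `adverse_deviation`.
`relsa_max` ties break to the earliest day, making reports deterministic.

## Estimation and testing

Group medians of RELSA_max (and of raw readouts) are estimated by a
nonparametric bootstrap: B = 10,000 resamples by default, estimator =
median of the resample medians, 95% percentile interval. Percentile is the
assumption-free default; BCa is available (`method="bca"`). All resampling
is driven by explicit integer seeds; identical seeds give bit-identical
results.

Hypothesis testing follows a branch: Shapiro–Wilk per group on the values
entering the comparison (raw-data mode; testing bootstrap distributions
instead is deliberately not the default, since their near-degeneracy makes
normality rejection automatic). Any group that is non-normal at α = 0.05,
constant, or smaller than 3 routes the whole comparison to the
nonparametric battery — Kruskal–Wallis omnibus (tie-corrected, mid-ranks),
pairwise two-sided Wilcoxon–Mann–Whitney (exact for small untied samples,
continuity-corrected normal approximation otherwise), Friedman for complete
subject × day blocks, and Dunn's z vs a control. The parametric battery is
one-way ANOVA or repeated-measures ANOVA with Greenhouse–Geisser sphericity
correction, plus Dunnett (between) or paired t (within) vs control. Every
pairwise family is Holm-adjusted; the family definitions are: all subgroup
pairs within one model per readout, and all model pairs in the between-model
comparison. Reports record the branch decision, seed, B and family so a
reader can audit every p-value. Stars follow *p ≤ 0.05, **p ≤ 0.01,
***p ≤ 0.001, ****p ≤ 0.0001 on the adjusted values.

Dunn's test is implemented in-package (pooled mid-ranks, tie-corrected
variance, two-sided normal p), cross-checked in the tests against
Wilcoxon–Mann–Whitney decisions in the two-group case.

## The synthetic-data generator

Each animal carries a latent distress trajectory s(t):

* acute: s(t) = (S + a)·exp(−λ·max(0, t − t_nadir)) for t ≥ 0, zero before
  the intervention — surgery-like insult with recovery;
* progressive: s(t) = (S + a)·(1 − exp(−λ·t)) — continuously worsening
  disease.

S is the profile severity, a ~ N(0, σ_animal) a shared per-animal random
effect (default σ = 0.12) that induces the cross-variable correlation the
composite exploits, λ the per-day rate (defaults 0.3–0.6). Readouts are
linear in the latent level with additive Gaussian noise, then rounded and
clamped for ordinal scales: body weight % = 100 − 12·s + ε (σ = 1.5),
burrowing % = 100 − 60·s + ε (σ = 8, floor 0, overshoot above 100 allowed),
nesting = clamp(round(6 − 3·s + ε), 1, 6) (σ = 0.4), distress =
clamp(round(5·s + ε), 0, 20) (σ = 0.6). The distress-score ceiling is
scoresheet-specific in practice and therefore a parameter (default 20).

The latent scale is calibrated so that the reference profile has S = 1:
with shared gains, the reference cohort's extremes are then ≈ one latent
unit per variable, and a disease cohort with severity S lands near S on the
composite scale. The four default profiles use S = 0.40 (CCl4, acute),
0.61 (PDA, acute), 0.70 (Pancreatitis, acute) and 1.10 (BDL, progressive)
— the published pooled severity medians of the four gastrointestinal
models, so the intended ordering CCl4 < PDA ≈ Pancreatitis < BDL is built
in at realistic effect sizes. The BDL profile draws extreme individuals
with probability 0.067 (≈ 2 of 30 animals) whose peak body-weight loss is
uniform in 22–32%, beyond the >20% humane endpoint; they remain in the
cohort until the horizon. Day grids are irregular by design: reference
−2…7 (nadir day 0), disease models −1…28 with sparser late sampling.

What the generator does **not** emulate: informative dropout after the
humane endpoint, day-to-day autocorrelated noise, floor effects in
burrowing at baseline, inter-laboratory scale shifts beyond the variable
subset, or missingness mechanisms other than "not measured that day".
Passing the recovery tests therefore shows the pipeline is sound under
idealised but realistically sized effects — not that it is robust to every
pathology of real husbandry data.

## Problem sizes in the validation suite

The bootstrap calibration check uses 500 replicates of n = 15 with
B = 2,000 (coverage of the true median must fall in 90–99%); the
ordering-recovery check uses 100 replicates of the four-model study at
n = 15 per model with B = 1,000 bootstrap resamples, under both the
3-variable and the 2-variable reference, requiring ≥ 95% recovery. The
acceptance script additionally runs one pooled study at n = 22/26/16/30
with B = 10,000. These sizes are the package's validation conditions and
are stated here so they can be scaled deliberately, not rediscovered.

## Numerical and degenerate-input choices

* Constant samples: Shapiro–Wilk is undefined; they report p = nan and
  force the nonparametric branch instead of erroring the pipeline.
  Kruskal–Wallis and Friedman on all-identical data return statistic 0,
  p = 1 by symmetry.
* Holm adjustment is order-preserving, capped at 1, with step-down
  monotonicity enforcement (delegated to statsmodels; hand-verified in the
  tests against first-principles step-down).
* Bootstrap of a constant sample collapses to a degenerate CI [c, c].
* Duplicate (animal, day, variable) rows, undeclared variables and
  non-increasing day grids are integrity errors at load time; unparseable
  numerics are reported with row context, never silently dropped. "NA" and
  empty cells are missing values.
* Wide (one column per variable) input tables are melted to the canonical
  long layout on load.

## Known limitations

* The composite combiner is a convention, not an identification result:
  different monotone combiners (e.g. weighted means) preserve the identities
  at 0 and 1 but can reorder intermediate animals. The pluggable combiner
  exists precisely to quantify that sensitivity.
* Percentile bootstrap CIs undercover slightly at n ≈ 15 for the median
  (the calibration band 90–99% reflects this); BCa narrows but does not
  remove the gap.
* No time-integrated ("cumulative suffering") score is provided: RELSA_max
  is a peak measure and deliberately ignores how long an animal stays
  distressed.
* Severity profiles are ordering-calibrated, not fitted to archived raw
  data; absolute synthetic medians track their configured severities only
  up to the noise and reference-sampling variability of each run.
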