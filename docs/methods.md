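# Methods

## Problem and data model

The package targets two-class tumor-subtype marker discovery from RPPA
protein panels. The expression input is a samples × proteins table of
level-4-style normalized abundances (log-like scale, arbitrary units)
with a per-sample subtype label; the clinical input carries age, sex,
stage (ordinal 1–4 after collapsing substages) and overall-survival
endpoints. Preprocessing drops proteins missing in strictly more than a
configurable fraction of samples (default one half; the boundary case is
kept), mean-imputes the remainder (pooled over both classes by default,
per-class optionally), and inner-joins clinical rows on a truncated
barcode prefix (default 15 characters, falling back to the 12-character
patient prefix when nothing matches). Mean imputation preserves every
protein's observed mean exactly; unmatched samples in a merge are
reported, never silently dropped.

## SNR filter

For protein j with class means μ₁, μ₂ and sample (n−1) standard
deviations σ₁, σ₂, `SNR_j = (μ₁ − μ₂)/(σ₁ + σ₂)`. Selection is on
`|SNR| > t` (strict, default t = 0.4): the magnitude is used because a
one-sided rule would discard every marker elevated in the second class,
while the filter's purpose is symmetric separation. A protein constant
in both classes has an undefined ratio and is never selected. Under the
generator's planted-effect model (class means ±δσ/2, common σ) the
population value is exactly δ/2, which anchors the calibration tests.

## BPSO wrapper selection

Particles are bit-masks over proteins. Velocity update
`v ← w·v + c₁R₁(pbest − x) + c₂R₂(gbest − x)` with independent uniform
R₁, R₂ per particle per coordinate, clamped to ±6 (sigmoid(6) ≈ 0.9975,
so bits always retain some flip probability); positions are *resampled*
bit-wise with probability `S(v) = 1/(1+e^{−v})`, not incremented.
Defaults: 500 particles, 50 iterations, w = 0.5, c₁ = 1, c₂ = 2.
Positions initialize Bernoulli(0.5), velocities zero. Personal and
global bests update on strict improvement, so the first achiever of a
fitness value keeps the record and ties break stably.

The wrapper fitness is stratified k-fold (default 5) cross-validated
accuracy of a pluggable base classifier on the masked features, minus
λ·(selected/total) with λ = 0.01 so equal-accuracy masks prefer fewer
proteins; the empty mask scores 0. The default learner is 5-nearest
neighbors on per-fold standardized features (training-fold statistics
only; RPPA scales differ across antibodies). Fold assignment is frozen
from the seed, making fitness a pure function of the mask — evaluations
are cached by mask bytes, which matters because a converging swarm
re-proposes the same masks heavily. Two runs with the same data, seed
and parameters are bit-identical.

## PC-stable structure learning

The skeleton phase starts from the complete graph over the selected
proteins plus the binary class node. At conditioning-level ℓ every
remaining edge a−b is tested against all size-ℓ subsets of the
*level-start* adjacency sets of a and of b (the stable rule), removing
the edge and recording the separating set on the first independence.
Unshielded triples a−c−b with c outside sepset(a, b) become colliders;
conflicting collider claims on one edge revert it to undirected with a
logged warning. Orientation then closes under the Meek rules R1–R3,
which are complete for patterns obtained from CI-based skeleton plus
collider discovery without background knowledge (the fourth rule only
fires when external orientation constraints exist, which this learner
does not accept). Node iteration is lexicographic everywhere, so results
are independent of column order both by construction and by the stable
rule.

CI testing is pluggable:

- `fisher_z` (default): partial correlation via precision-matrix
  inversion of the joint correlation submatrix, statistic
  `√(n−|S|−3)·atanh(r)`, two-sided normal p-value. The class enters as
  0/1 numeric. A singular conditioning matrix makes the pair
  conservatively dependent. The maximum conditioning size is capped at
  n−4.
- `g2_disc`: per-variable 3-quantile discretization (variables with ≤3
  distinct values kept as-is), G² = 2·ΣO·ln(O/E) summed within every
  configuration of the conditioning variables, df =
  (r_a−1)(r_b−1)·Πr_s. *Limitation:* coarse discretization of a
  continuous conditioning variable leaves residual within-bin
  dependence, so on strong continuous chains the G² route can keep an
  edge that Fisher-z removes; it is intended for discrete or
  discretization-faithful data, which is why Fisher-z is the default.
- `OracleTester`: exact CI decisions from a population covariance
  (partial correlation compared against a tolerance), used to validate
  structural recovery independent of sampling noise.

`direct_markers` reads off the class node's neighbors (any edge kind,
annotated with orientation, name-sorted). Significance level α defaults
to 0.05 for data analysis; the structural-recovery benchmarks use 0.01
to keep the family-wise false-edge rate low across the many tests.

## Validation statistics

- Wilcoxon rank-sum: exact null enumeration when both groups have ≤6
  observations and no cross-group ties, otherwise normal approximation
  with tie and continuity correction (scipy backend); reported statistic
  is the first group's rank sum.
- Spearman correlation: tie-aware average ranks, two-sided p,
  complete-case; constant inputs yield an undefined rho rather than an
  error.
- Cox proportional hazards: univariate partial-likelihood fit via
  lifelines (Efron tie handling), hazard ratio per unit covariate with
  Wald 95% CI. Stage enters as ordinal 1–4, age as continuous years, sex
  as male = 1 with the coding printed in the row label. Perfectly
  separating covariates follow the monotone-likelihood path and surface
  as extreme HRs rather than hard failures.
- Kaplan-Meier / log-rank: product-limit curves per group via lifelines;
  continuous markers are dichotomized at the median (the package's
  cutpoint convention — no optimal-cutpoint search). With no censoring
  the estimate equals the empirical survival function exactly.
- PCA: columns centered and (by default) scaled to unit variance;
  variance percentages are eigenvalues over their total × 100, matching
  a direct eigendecomposition of the correlation matrix to 1e-10.
  Zero-variance columns are dropped under standardization with a
  warning.
- t-SNE: presentation only; seeded, PCA-initialized, perplexity must be
  below (n−1)/3.

## Synthetic-data generator

The generator defines the package's test conditions and mirrors the
structure, not the full messiness, of RPPA cohorts:

- **Expression:** Gaussian abundances on a log-like scale; informative
  protein k gets class means ±δ_k·σ/2 with common σ (population SNR
  δ_k/2); classes are balanced by default with 200 samples per class,
  matching the near-balanced cohorts these panels typically have.
  Missingness is completely at random (rate ≤ 0.5, optionally targeted
  at chosen columns to exercise the filter).
- **Structural equation models:** linear-Gaussian equations in
  topological order; the binary class node is logistic in its parents,
  or Bernoulli(0.5) at a root with its continuous children shifted by
  the edge coefficient. The returned ground truth is the DAG's CPDAG
  (its v-structures plus Meek closure) — the identifiable object a
  CI-based learner can at best recover.
- **Survival:** Weibull proportional hazards (default shape 1.5, scale
  1000 days), linear predictor from named covariates' log hazard
  ratios, independent Uniform(0, c_max) censoring with c_max calibrated
  by bisection of E[fraction censored] to the target (default 30%,
  typical of lung-cohort follow-up).

Not emulated: protein–protein correlation beyond the configured DAG,
heavy-tailed or batch-structured noise, informative missingness, and
cohort-level class imbalance beyond the config knob. Passing tests
therefore demonstrate correctness of the algorithms under their stated
assumptions, not robustness to every artifact of production RPPA data.

## Numerical and design choices

- Sample (n−1) standard deviations throughout; strict inequalities at
  the SNR threshold and the missingness boundary.
- Velocity clamp ±6; sigmoid computed with the numerically stable
  two-branch form (scipy `expit`).
- Seed fan-out: a single pipeline seed derives per-stage sub-seeds as
  the first four bytes of SHA-256("seed:stage") mod 2³¹, so stages are
  individually reproducible and mutually decorrelated.
- Benchmark problem sizes (5000 samples for CPDAG recovery and SNR
  calibration, 2000 for Cox recovery, 200/class with a 60×40 swarm for
  planted-feature recovery) were chosen as the smallest scales at which
  the corresponding population quantities are estimated with comfortable
  margin; they keep the full suite and the acceptance script to minutes
  on one CPU.
- Degenerate inputs fail loudly and early: single-class data,
  all-missing columns reaching imputation, empty groups, no observed
  events, perplexity out of range, cyclic DAG specs.

## Known limitations

- The wrapper fitness is the package's own design; with a different
  base learner or penalty the selected subset can differ — the paper
  trail of any real analysis should report the `FitnessSpec` used.
- Fisher-z treats the binary class as numeric, which is standard
  practice but approximate; the G² route exists for fully discrete
  analyses and carries the discretization caveat above.
- No batch correction, no multivariate Cox adjustment, no
  optimal-cutpoint survival splits, no bootstrap edge confidence on the
  network.
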