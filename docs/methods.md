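# Methods

This note documents the statistical machinery in `benchval`: the model behind
each component, the conventions and parameter choices, and the places where a
design decision was required and why it was resolved the way it was.

## 1. Single-fold AUC uncertainty (`benchval.auc`)

**WMW identity.** The empirical AUC-ROC of a fold equals the normalized
Wilcoxon–Mann–Whitney statistic: the fraction of (positive, negative) pairs
ranked correctly, with ties credited 0.5. `auc_wmw` computes it from midranks
(`scipy.stats.rankdata`), so tied scores are handled exactly; the test suite
cross-checks it against brute-force pair counting and against
`sklearn.metrics.roc_auc_score`.

**Hanley–McNeil interval.** For a fold with `n_pos` and `n_neg` members and
observed AUC `A`, the Hanley–McNeil standard error uses
`Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)`:

```
SE² = [A(1−A) + (n_pos−1)(Q1−A²) + (n_neg−1)(Q2−A²)] / (n_pos · n_neg)
```

The interval is `A ± z·SE`, truncated to [0, 1]. It is an asymptotic normal
interval: at `A = 1` the SE degenerates to zero width, and with fewer than
two members in either class the variance components lose their degrees of
freedom, so `hanley_mcneil_ci` refuses degenerate folds
(`DegenerateFoldError`) rather than returning a meaningless interval.

**Exact enumeration.** For tiny folds, `enumerate_auc_distribution` lists the
AUC of every equally likely placement of the positives among the ranks
(`C(n, n_pos)` placements) and returns the exact discrete distribution of the
AUC of a uniformly random ranking. With 2 actives and 1 inactive the support
is exactly {0, 0.5, 1} with SD ≈ 0.41 — the whole AUC scale. Enumeration is
capped at 20 samples per fold; beyond that the simulation path applies.

**Degenerate-fold simulation interval.** `simulate_degenerate_ci` reports a
percentile interval for the AUC of a fold whose composition makes the normal
interval unusable. The default method is *label permutation*: holding the
fold composition fixed, scores are randomly re-ranked, which samples the
random-ranking AUC distribution — the honest statement of how little such a
fold constrains the AUC (for a fold with one active and 29 inactives the 95%
interval is essentially (0, 1)). A stratified within-class bootstrap is
available as `method="bootstrap"`; it was considered as the default but
rejected, because resampling within a singleton class is a no-op and the
resulting intervals collapse (zero width when the singleton class determines
every pair) instead of widening. Permutation is the default because the
question these folds pose is "what could a ranking of this composition
yield", not "how variable is this particular score sample".

**Fold aggregation.** `mean_sem_across_folds` uses the population-SD
convention, `SEM = SD(ddof=0)/√k`, matching how benchmark tables typically
report mean ± SEM over k folds. `mean_ci_t2` forms `mean ± t(0.975, df=2)·SEM`
for exactly three folds (t = 4.30), the honest small-sample interval.

## 2. Cross-assay comparison (`benchval.comparison`)

**Benchmark tables.** `BenchmarkTable` wraps a long-format DataFrame
(`assay_id, model, fold, auc_roc, auc_pr, n_pos, n_neg`) and validates it on
construction: AUCs in [0, 1], no duplicate cells, every model evaluated on
the same folds with the same class composition per (assay, fold). CSV
round-trips are exact.

**Effect sizes.** `cohens_d(mu1, mu2, s1, s2)` returns
`(mu2 − mu1)/√((s1² + s2²)/2)`; `cohens_d_from_sem` converts reported SEMs
back to fold-level SDs via `s = SEM·√k`. Effect sizes are the antidote to
raw AUC differences: +0.03 AUC is d ≈ 4.4 between two precisely measured
models and d ≈ 0.55 between two noisy ones.

**Sign test with Wilson interval.** `sign_test_wilson` counts wins for model
A over model B per fold or per assay mean, drops ties (reported), and wraps
the win proportion in a Wilson score interval
(`statsmodels.stats.proportion.proportion_confint`). The Wilson interval is
used instead of the Wald interval for its small-sample and boundary behavior.
A "significant" comparison is one whose interval excludes 0.5.

**Wilcoxon signed-rank, and why it can mislead.** `wilcoxon_signed_rank`
computes W = sum of signed ranks of the paired differences. For ≤ 25 nonzero
differences the p-value is exact, from a subset-sum dynamic program over the
doubled ranks (ties make ranks half-integral; doubling keeps the DP integral);
larger samples use the normal approximation with `Var(W) = Σ r²`. Both paths
are cross-checked against `scipy.stats.wilcoxon`. The statistic ranks
differences by raw magnitude and ignores per-assay uncertainty, so many tiny
noisy assays with large raw margins can outvote a smaller number of large,
precisely measured assays pointing the other way. `paradox_benchmark`
constructs exactly this situation, and the test suite asserts that W and the
large-assay effect sizes disagree on it. The default precondition requires at
least 5 nonzero differences (`min_n`), relaxable for worked examples.

**Win tables.** `win_table` reports the percentage of test folds on which
each model is strictly best (ties bucketed separately);
`size_stratified_wins` restricts the win rate to assays above a test-size
threshold, where fold AUCs are actually informative.

## 3. Metric behavior under imbalance (`benchval.metric_sim`)

A *theoretical classifier* is a pair of score distributions (normal or beta)
for actives and inactives. Sampling e.g. 100 actives against 10,000
inactives (a 1% hit rate) and computing ROC, precision–recall, and
enrichment-factor curves exposes what each metric sees:

- Two equal-variance Gaussians N(0.4, 0.1) vs N(0.6, 0.1) have closed-form
  AUC `Φ((μ⁺−μ⁻)/(σ√2)) ≈ 0.921` (`gaussian_auc_closed_form`, used as an
  oracle).
- A Beta(3, 1) active distribution against the same inactives has nearly the
  same AUC-ROC but concentrates actives near the top of the ranking: AUC-PR
  roughly triples and the top-1% enrichment factor roughly doubles.

AUC-PR defaults to average precision (the step-function integral,
`sklearn.metrics.average_precision_score`); the trapezoidal PR area is
available but linear interpolation between PR operating points is a
different estimator and the two genuinely disagree. The random baseline for
AUC-PR is the prevalence `n_pos/(n_pos+n_neg)` — with one caveat measured
during validation: the *null* average precision has a positive finite-sample
excess over the prevalence (≈ +0.010 at 50/500, decaying roughly like
1/n_pos), so tests assert convergence, not small-sample equality.

`enrichment_factor(fold, x)` is the fraction of all actives in the top
`ceil(x·N)` of the ranked list divided by `x`; 1 is random, and the maximum
is capped by exhausting the actives.

## 4. CV interval coverage (`benchval.cv_sim`)

The experiment asks: when a benchmark reports "mean ± t·SEM" from 3-fold CV,
how often does that interval contain the true generalization performance?

Model: two spherical unit-variance Gaussians in `dim = 100` dimensions
(high-dimensional relative to `n_train = 300`), class means separated along
one axis. The classifier is the canonical linear max-margin classifier — a
hinge-loss SVM, `sklearn.svm.SVC(kernel="linear")` with C = 1, no tuning
inside CV. (The squared-hinge `LinearSVC` variant was measured too and
undercovers slightly more, 75.7–76.4% vs ≈ 77–79%; the hinge-loss SVC is
used because it is the standard definition of a linear SVM.)

`calibrate_separation` bisects on the class separation until the mean
large-test AUC of freshly trained classifiers (≥ 50 pilot runs per
evaluation) is within 0.005 of the 0.75 target; AUC is monotone in the
separation, so bisection is valid up to pilot noise.

Each of 1000 runs then: draws a fresh 300-sample training set, trains, and
records the AUC on a fresh 10,000-sample test set as the truth; runs
stratified 3-fold CV on the same 300 samples and forms
`mean ± t(0.975, df=2)·SEM`. Coverage is the fraction of runs whose interval
contains the truth. Per-run randomness comes from `numpy` `SeedSequence`
substreams spawned from one master seed, so the whole experiment is
reproducible and runs are independent.

Findings the test suite asserts: nominal-95% intervals cover only ≈ 76–79%
of the time (folds share training data, so fold AUCs are positively
correlated and the SEM understates the spread); plain ±2·SEM intervals are
far worse (≈ 48%); single CV estimates miss the truth by more than 0.05 AUC
in a non-negligible share of runs; and the CV mean is *pessimistically*
biased (mean error ≈ −0.035) because each fold trains on two-thirds of the
data.

## 5. Synthetic benchmarks (`benchval.synthetic`)

`generate_benchmark` produces assay × model × fold AUC tables with known
ground truth, emulating the statistical shape of large public bioactivity
benchmarks. The defaults are this package's own modeling choices:

- assay sizes log-uniform on [100, 30,000];
- three folds of unequal size (Dirichlet(4) partition);
- per-fold active fractions from Beta(2, 5) (mean ≈ 0.29), with probability
  0.126 that an assay receives one inverted-skew fold (≥ 90% actives);
- latent fold AUCs on the probit scale: a per-assay random effect
  (SD 0.35) around a base AUC of 0.8, plus per-model offsets and optional
  planted structure — a per-assay favored model (`advantage_prob`), per-fold
  favorites with known frequencies (`fold_favorite_probs`), or a
  size-dependent advantage (`size_slope`).

Crucially, fold AUCs are *not* "latent AUC plus Gaussian noise": each fold's
AUC is computed by sampling scores from a binormal model
(negatives N(0,1), positives N(δ,1) with `δ = √2·Φ⁻¹(AUC)`) and running the
WMW statistic, so small folds exhibit the discreteness, bounded support, and
skew that real fold AUCs have. The latent parameters are returned as ground
truth for parameter-recovery tests. `inject_degenerate_folds` replaces a
fraction of folds with tiny compositions (default 2 actives / 1 inactive) to
force downstream code through the enumeration/simulation paths, and
`paradox_benchmark` builds the signed-rank-vs-effect-size disagreement
described above.

For speed, the generator computes average precision with an internal
vectorized implementation; the test suite asserts it exactly equal to
scikit-learn's on heavily tied and untied folds. User-facing curve
computation (`benchval.metric_sim.curves`) uses scikit-learn directly.

## 6. Numerical and reproducibility choices

- Every randomized entry point takes an explicit seed; long experiments
  spawn independent per-run substreams via `numpy.random.SeedSequence`.
  Reruns with the same inputs are byte-identical, including CLI outputs.
- Exact quantities (closed-form intervals, enumeration, effect sizes) are
  computed in closed form, never by simulation; simulations are reserved for
  quantities that are stochastic by definition and always report the number
  of repetitions behind them.
- Curve areas are clamped to [0, 1] to absorb trapezoid round-off at the
  boundaries.
- Text reports round to 2–3 decimals; machine-readable outputs keep full
  precision.

## 7. Limitations

- The Hanley–McNeil interval is asymptotic: it collapses at AUC = 1 and is
  refused (rather than patched) for degenerate folds. Exact small-sample
  intervals for non-degenerate folds are out of scope.
- The CV coverage number depends on the data model, classifier, and
  dimensionality; ≈ 76–79% is specific to this calibrated Gaussian setup,
  and the qualitative claim (undercoverage from correlated folds) is the
  portable part.
- The synthetic generator is a statistical emulation — it reproduces the
  *shape* of benchmark tables (sizes, imbalance, fold structure, planted
  winners), not any particular dataset's chemistry.
- `load_external_results` maps a published external results schema into a
  `BenchmarkTable`, but the download is not bundled and the loader is not
  exercised in CI; analyses that require those data are documented as
  out-of-scope for the test suite.
- The sign test treats assays (or folds) as exchangeable units; fold-level
  comparisons within an assay are correlated, so fold-unit intervals are
  anti-conservative and the assay-mean unit is the defensible default for
  inference.
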