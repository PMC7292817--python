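# benchval

Uncertainty-aware statistics for classifier benchmarks.

Large bioactivity benchmarks routinely rank machine-learning models by mean
AUC-ROC across hundreds of assays and declare a winner from the third decimal
place. Much of that precision is illusory: test folds with a handful of
actives produce AUCs that can only take a few discrete values, fold-level
standard errors are rarely reported, cross-validation intervals undercover
because folds share training data, and AUC-ROC itself is blind to the early
retrieval behavior that matters in a virtual screen. `benchval` packages the
statistics needed to take benchmark tables apart honestly:

- **Single-fold AUC uncertainty** — the Wilcoxon–Mann–Whitney AUC, the
  Hanley–McNeil closed-form confidence interval, exact enumeration of the
  achievable AUCs of tiny folds, and a simulation interval for degenerate
  folds where the asymptotics fail (`benchval.auc`).
- **Cross-assay model comparison** — per-assay mean ± SEM aggregation,
  Cohen's d effect sizes, a sign test with a Wilson score interval, a
  Wilcoxon signed-rank test with an exact small-sample null, win tables, and
  size-stratified win rates (`benchval.comparison`).
- **Metric behavior under imbalance** — simulations of theoretical
  classifiers showing how AUC-PR and enrichment factors separate models that
  AUC-ROC cannot (`benchval.metric_sim`).
- **Cross-validation interval coverage** — a calibrated synthetic experiment
  measuring how often "mean ± t·SEM" from 3-fold CV actually covers the true
  generalization AUC (`benchval.cv_sim`).
- **Synthetic benchmarks with known ground truth** — a generator for
  assay × model × fold AUC tables with realistic size and class-balance
  structure, planted winners, and degenerate-fold injection, for validating
  any of the above end to end (`benchval.synthetic`).

## Worked example

How much certainty does one fold's AUC actually carry?

```python
>>> from benchval import hanley_mcneil_ci
>>> print(hanley_mcneil_ci(0.889, n_pos=5553, n_neg=13855))
0.889 (0.883, 0.895)
```

A large fold pins the AUC down to about ±0.006. A tiny fold does not — with
2 actives and 1 inactive the AUC of even a random classifier can only be
0, 0.5, or 1:

```python
>>> from benchval import enumerate_auc_distribution
>>> dist = enumerate_auc_distribution(n_pos=2, n_neg=1)
>>> dist.values, dist.mean, round(dist.sd, 2)
(array([0. , 0.5, 1. ]), 0.5, 0.41)
```

For degenerate folds too large to enumerate, a simulation interval shows the
honest answer is often "anywhere":

```python
>>> import numpy as np
>>> from benchval import ScoreSet, simulate_degenerate_ci
>>> rng = np.random.default_rng(0)
>>> fold = ScoreSet.from_pos_neg(rng.random(1), rng.random(29))  # 1 active
>>> print(simulate_degenerate_ci(fold, seed=0))
0.517 (0.000, 1.000)
```

Effect sizes put fold-level spread back into model comparisons. A difference
of 0.03 AUC can be enormous — or noise — depending on the SEMs:

```python
>>> from benchval import cohens_d_from_sem
>>> round(cohens_d_from_sem(0.900, 0.929, sem1=0.005, sem2=0.002, n_folds=3).d, 2)
4.4
```

And two classifiers with the same AUC-ROC can behave completely differently
where it counts (100 actives vs 10,000 inactives, 10 replicates):

```python
>>> from benchval import overlapping_gaussians_spec, early_retrieval_spec, run_replicates
>>> broad = run_replicates(overlapping_gaussians_spec(reps=10, seed=0))
>>> early = run_replicates(early_retrieval_spec(reps=10, seed=0))
>>> [round(x, 3) for x in (broad.mean_auc_roc, early.mean_auc_roc)]   # AUC-ROC: tied
[0.919, 0.915]
>>> [round(x, 3) for x in (broad.mean_auc_pr, early.mean_auc_pr)]     # AUC-PR: not
[0.252, 0.719]
>>> [round(x, 1) for x in (broad.mean_ef(0), early.mean_ef(0))]       # EF at top 1%
[29.7, 68.6]
```

## Command line

The same machinery is exposed as a `benchval` command:

```sh
$ benchval auc-ci --auc 0.889 --n-pos 5553 --n-neg 13855
0.889 (0.883, 0.895)  [hanley_mcneil, 95% CI]

$ benchval generate-benchmark --out bench.csv --truth truth.json --seed 8
wrote 600 records (100 assays x 2 models x 3 folds) -> bench.csv

$ benchval compare --table bench.csv --models FNN SVM --unit assay
$ benchval win-table --table bench.csv
$ benchval simulate-metrics --config spec.yaml --out curves/
$ benchval simulate-cv --runs 1000 --out coverage.json
```

All randomized subcommands take an explicit `--seed` and echo their full
configuration into the output, so reruns are byte-identical.

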