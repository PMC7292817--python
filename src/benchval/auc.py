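"""Empirical AUC-ROC for a single test fold and its uncertainty.

The area under the ROC curve equals the Wilcoxon-Mann-Whitney statistic:
the probability that a randomly chosen active (positive) is ranked above a
randomly chosen inactive (negative), with tied scores credited 1/2.  For
large folds the Hanley-McNeil closed-form standard error gives a normal
confidence interval; for tiny or heavily imbalanced ("degenerate") folds
the interval is obtained instead by exact enumeration of the achievable AUC
values or by simulation, because the effective degrees of freedom cannot be
computed when a class has fewer than two members.

Fold aggregation follows the benchmark convention used throughout the
package: the standard error of the mean across k folds is the population
standard deviation (divisor k) over sqrt(k), and 95% intervals for 3-fold
means use a t distribution with 2 degrees of freedom.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "ScoreSet",
    "AUCEstimate",
    "AUCDistribution",
    "UndefinedAUCError",
    "DegenerateFoldError",
    "auc_wmw",
    "hanley_mcneil_ci",
    "enumerate_auc_distribution",
    "simulate_degenerate_ci",
    "mean_sem_across_folds",
    "mean_ci_t2",
    "read_scores",
]


class UndefinedAUCError(ValueError):
    """AUC is undefined: the fold has no positives or no negatives."""


class DegenerateFoldError(ValueError):
    """Closed-form interval unavailable; use enumeration or simulation."""


@dataclass(frozen=True)
class ScoreSet:
    """One test fold: classifier scores with binary activity labels.

    Labels are 1 for actives (the positive class, as conventional in the
    drug-discovery literature) and 0 for inactives.
    """

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        if scores.ndim != 1 or labels.ndim != 1:
            raise ValueError("scores and labels must be one-dimensional")
        if scores.shape != labels.shape:
            raise ValueError("scores and labels must have the same length")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = inactive, 1 = active)")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels.astype(np.int8))

    @classmethod
    def from_pos_neg(cls, pos_scores, neg_scores) -> "ScoreSet":
        pos = np.asarray(pos_scores, dtype=float)
        neg = np.asarray(neg_scores, dtype=float)
        return cls(
            scores=np.concatenate([pos, neg]),
            labels=np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]),
        )

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    @property
    def pos_scores(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    @property
    def neg_scores(self) -> np.ndarray:
        return self.scores[self.labels == 0]

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class AUCEstimate:
    """An AUC value with standard error and confidence interval.

    ``method`` records how the interval was produced: ``hanley_mcneil``
    (closed-form normal approximation), ``enumeration`` (exact
    small-sample distribution), or ``simulation`` (resampling).
    """

    auc: float
    se: float | None
    ci_low: float
    ci_high: float
    level: float
    method: str

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")
        if not 0.0 <= self.ci_low <= self.ci_high <= 1.0:
            raise ValueError("interval must satisfy 0 <= low <= high <= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
            "method": self.method,
        }

    def __str__(self) -> str:  # Table-style rendering, 3 decimals
        return f"{self.auc:.3f} ({self.ci_low:.3f}, {self.ci_high:.3f})"


@dataclass(frozen=True)
class AUCDistribution:
    """Exact distribution of the AUC of a uniformly random ranking."""

    values: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(
            self, "probabilities", np.asarray(self.probabilities, dtype=float)
        )
        if not math.isclose(self.probabilities.sum(), 1.0, abs_tol=1e-12):
            raise ValueError("probabilities must sum to 1")

    @property
    def mean(self) -> float:
        return float(self.values @ self.probabilities)

    @property
    def sd(self) -> float:
        m = self.mean
        return float(np.sqrt(((self.values - m) ** 2) @ self.probabilities))


def auc_wmw(fold: ScoreSet) -> float:
    """AUC-ROC of one fold as the normalized Wilcoxon-Mann-Whitney statistic.

    Counts correctly ordered positive/negative score pairs, crediting 1/2
    for each tied pair, over all n_pos * n_neg pairs.  Computed through
    midranks, which is O(n log n) and exactly equivalent to pair counting.
    """
    n_pos, n_neg = fold.n_pos, fold.n_neg
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"AUC undefined for a fold with {n_pos} positives and {n_neg} "
            "negatives: both classes must be represented"
        )
    ranks = rankdata(fold.scores)
    u = ranks[fold.labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC.

    Uses the exponential-distribution approximations Q1 = A/(2-A) and
    Q2 = 2A^2/(1+A) from the original 1982 derivation.
    """
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    # roundoff can push the variance a hair below zero at auc = 0 or 1
    return math.sqrt(max(var, 0.0))


def hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> AUCEstimate:
    """Closed-form normal-approximation confidence interval for an AUC.

    Requires at least two members of each class so that the effective
    degrees of freedom are computable; smaller folds must go through
    :func:`enumerate_auc_distribution` or :func:`simulate_degenerate_ci`.
    The interval is symmetric on the SE scale and truncated to [0, 1].
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if n_pos < 2 or n_neg < 2:
        raise DegenerateFoldError(
            f"degrees of freedom not computable for {n_pos} positives / "
            f"{n_neg} negatives; use enumerate_auc_distribution or "
            "simulate_degenerate_ci for degenerate folds"
        )
    se = _hanley_mcneil_se(auc, n_pos, n_neg)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return AUCEstimate(
        auc=auc,
        se=se,
        ci_low=max(0.0, auc - z * se),
        ci_high=min(1.0, auc + z * se),
        level=level,
        method="hanley_mcneil",
    )


def enumerate_auc_distribution(
    n_pos: int, n_neg: int, max_total: int = 20
) -> AUCDistribution:
    """Exact AUC distribution of a uniformly random ranking of a fold.

    Enumerates all C(n_pos + n_neg, n_pos) equally likely placements of the
    positives within the ranking and tallies the resulting WMW AUC values.
    A fold of 2 actives and 1 inactive, for instance, can only achieve
    AUC in {0, 0.5, 1}; the mean is 0.5 for any composition.
    """
    if n_pos < 1 or n_neg < 1:
        raise UndefinedAUCError("need at least one member of each class")
    total = n_pos + n_neg
    if total > max_total:
        raise ValueError(
            f"fold size {total} exceeds the enumeration cap {max_total}; "
            "use simulate_degenerate_ci (Monte Carlo) instead"
        )
    n_pairs = n_pos * n_neg
    counts: dict[int, int] = {}
    # positions are ranks 0..total-1 (ascending); U = sum(pos_rank_i - i)
    for placement in itertools.combinations(range(total), n_pos):
        u = sum(p - i for i, p in enumerate(placement))
        counts[u] = counts.get(u, 0) + 1
    n_placements = math.comb(total, n_pos)
    us = sorted(counts)
    values = np.array([u / n_pairs for u in us])
    probs = np.array([counts[u] / n_placements for u in us])
    return AUCDistribution(values=values, probabilities=probs)


def simulate_degenerate_ci(
    fold: ScoreSet,
    level: float = 0.95,
    reps: int = 10_000,
    seed: int = 0,
    method: str = "permutation",
) -> AUCEstimate:
    """Simulation-based interval for a degenerate fold's AUC.

    ``method="permutation"`` (default) takes percentile bounds of the AUC
    distribution of a random ranking at the fold's composition — i.e. the
    spread of AUC values the fold could produce by chance.  For a fold with
    one active among 30 compounds this spans essentially all of [0, 1],
    which is the point: any single AUC value from such a fold is nearly
    meaningless.  ``method="bootstrap"`` instead resamples scores with
    replacement within each class (stratified bootstrap) and takes
    percentile bounds; note it degenerates when a class has one member.

    Deterministic under a fixed ``seed``.
    """
    n_pos, n_neg = fold.n_pos, fold.n_neg
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: a class is empty")
    if reps < 1000:
        raise ValueError("reps must be at least 1000 for stable percentiles")
    rng = np.random.default_rng(seed)
    point = auc_wmw(fold)
    n = len(fold)
    if method == "permutation":
        ranks = rankdata(fold.scores)
        offset = n_pos * (n_pos + 1) / 2.0
        # random placements of the positive labels over the observed ranks
        picks = np.argsort(rng.random((reps, n)), axis=1)[:, :n_pos]
        aucs = (ranks[picks].sum(axis=1) - offset) / (n_pos * n_neg)
    elif method == "bootstrap":
        pos, neg = fold.pos_scores, fold.neg_scores
        aucs = np.empty(reps)
        for i in range(reps):
            bs = ScoreSet.from_pos_neg(
                rng.choice(pos, size=n_pos, replace=True),
                rng.choice(neg, size=n_neg, replace=True),
            )
            aucs[i] = auc_wmw(bs)
    else:
        raise ValueError(f"unknown method {method!r}")
    lo, hi = np.quantile(aucs, [0.5 - level / 2.0, 0.5 + level / 2.0])
    return AUCEstimate(
        auc=point,
        se=float(np.std(aucs)),
        ci_low=float(max(0.0, lo)),
        ci_high=float(min(1.0, hi)),
        level=level,
        method="simulation",
    )


def mean_sem_across_folds(fold_aucs) -> tuple[float, float]:
    """Mean and standard error of the mean over fold-level AUC values.

    The SEM uses the population standard deviation (divisor k) over
    sqrt(k), the convention of the benchmark tables this package targets.
    """
    vals = np.asarray(fold_aucs, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two folds to form a mean and SEM")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=0) / math.sqrt(vals.size))
    return mean, sem


def mean_ci_t2(fold_aucs, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a 3-fold mean AUC via t with 2 df.

    mean +/- t(df=2, level) * SEM, truncated to [0, 1].  Fixed to exactly
    three folds; generalizing the degrees of freedom is out of scope.
    """
    vals = np.asarray(fold_aucs, dtype=float)
    if vals.size != 3:
        raise ValueError("mean_ci_t2 is defined for exactly 3 folds (df = 2)")
    mean, sem = mean_sem_across_folds(vals)
    t = stats.t.ppf(0.5 + level / 2.0, df=2)
    return (max(0.0, mean - t * sem), min(1.0, mean + t * sem))


def read_scores(path, delimiter: str | None = None) -> ScoreSet:
    """Read a two-column delimited text file of (score, label in {0,1})."""
    arr = np.loadtxt(Path(path), delimiter=delimiter, ndmin=2)
    if arr.shape[1] != 2:
        raise ValueError("expected exactly two columns: score, label")
    return ScoreSet(scores=arr[:, 0], labels=arr[:, 1].astype(int))
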