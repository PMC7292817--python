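"""Does k-fold cross-validation honestly report its own uncertainty?

The experiment: draw a training set from two spherical Gaussians whose
separation is calibrated so a linear max-margin classifier reaches a
target generalization AUC-ROC (default 0.75); record the trained model's
AUC on a large fresh test set as the truth; run stratified k-fold CV on
the same training samples and form a confidence interval
mean +/- t(df=k-1) * SEM from the fold AUCs.  Repeating this many times
measures how often the CV interval actually covers the truth.  Because
CV folds share training data, the fold AUCs are positively correlated and
the intervals undercover — at n_train=300 with 3 folds, nominal-95%
intervals cover the truth only about 80% of the time, and plain
+/- 2*SEM intervals do even worse.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .auc import ScoreSet, auc_wmw, mean_sem_across_folds

__all__ = [
    "CVSimConfig",
    "CoverageReport",
    "make_gaussian_dataset",
    "calibrate_separation",
    "evaluate_true_auc",
    "run_cv_experiment",
]


@dataclass(frozen=True)
class CVSimConfig:
    """Configuration of the CV coverage experiment.

    ``dim`` is the feature dimensionality of the synthetic Gaussians
    (default 100: high-dimensional relative to n_train).  ``separation``
    is the distance between the class means; leave ``None`` to calibrate
    it to ``target_auc`` via :func:`calibrate_separation`.
    """

    n_train: int = 300
    n_test: int = 10_000
    dim: int = 100
    target_auc: float = 0.75
    k: int = 3
    runs: int = 1000
    level: float = 0.95
    seed: int = 0
    separation: float | None = None
    calibration_runs: int = 60
    calibration_tol: float = 0.005

    def __post_init__(self):
        if self.n_train < self.k:
            raise ValueError("n_train must be at least k")
        if not 0.5 < self.target_auc < 1.0:
            raise ValueError("target_auc must lie in (0.5, 1)")
        if self.dim < 1:
            raise ValueError("dim must be at least 1")


def make_gaussian_dataset(
    dim: int, separation: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced sample from two spherical unit-variance Gaussians.

    Class means sit at the origin and at ``separation`` along the first
    axis; labels are balanced (n must be even).
    """
    if dim < 1:
        raise ValueError("dim must be at least 1")
    if n < 2 or n % 2:
        raise ValueError("n must be an even count >= 2 (balanced classes)")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    X = rng.standard_normal((n, dim))
    y = np.zeros(n, dtype=np.int8)
    y[n // 2 :] = 1
    X[y == 1, 0] += separation
    perm = rng.permutation(n)
    return X[perm], y[perm]


def _new_classifier() -> SVC:
    # canonical hinge-loss linear SVM, conventional C=1, no tuning inside CV
    return SVC(kernel="linear", C=1.0)


def _single_run_true_auc(
    cfg: CVSimConfig, separation: float, rng: np.random.Generator
) -> float:
    Xtr, ytr = make_gaussian_dataset(cfg.dim, separation, cfg.n_train, rng)
    clf = _new_classifier().fit(Xtr, ytr)
    Xte, yte = make_gaussian_dataset(cfg.dim, separation, cfg.n_test, rng)
    scores = clf.decision_function(Xte)
    return auc_wmw(ScoreSet(scores=scores, labels=yte))


def evaluate_true_auc(
    cfg: CVSimConfig, separation: float, n_runs: int, seed: int
) -> np.ndarray:
    """Large-test AUC of freshly trained classifiers over independent runs."""
    streams = np.random.SeedSequence(seed).spawn(n_runs)
    return np.array(
        [
            _single_run_true_auc(cfg, separation, np.random.default_rng(s))
            for s in streams
        ]
    )


def calibrate_separation(
    cfg: CVSimConfig, bracket: tuple[float, float] = (0.05, 4.0)
) -> float:
    """Find the class separation at which the trained classifier attains
    the target generalization AUC.

    Bisection on the mean large-test AUC of classifiers trained on
    ``n_train`` samples, estimated over ``calibration_runs`` pilot runs per
    evaluation; stops once the pilot mean is within ``calibration_tol`` of
    the target or the bracket is below 1e-3.  Monotonicity of AUC in the
    separation makes bisection valid up to pilot noise.
    """
    if cfg.calibration_runs < 50:
        raise ValueError("use at least 50 pilot runs per evaluation")
    lo, hi = bracket
    rng_seed = np.random.SeedSequence([cfg.seed, 0xCA1]).generate_state(1)[0] % (
        2**31
    )

    def pilot_mean(sep: float, tag: int) -> float:
        return float(
            evaluate_true_auc(
                cfg, sep, cfg.calibration_runs, seed=rng_seed + tag
            ).mean()
        )

    f_lo = pilot_mean(lo, 1)
    f_hi = pilot_mean(hi, 2)
    if not (f_lo < cfg.target_auc < f_hi):
        raise ValueError(
            f"bracket {bracket} does not enclose target {cfg.target_auc}: "
            f"pilot AUCs ({f_lo:.3f}, {f_hi:.3f})"
        )
    for it in range(40):
        mid = 0.5 * (lo + hi)
        f_mid = pilot_mean(mid, 3 + it)
        if abs(f_mid - cfg.target_auc) <= cfg.calibration_tol or hi - lo < 1e-3:
            return mid
        if f_mid < cfg.target_auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class CoverageReport:
    """Per-run CV estimates vs truth, and interval coverage."""

    config: CVSimConfig
    separation: float
    cv_means: np.ndarray
    cv_sems: np.ndarray
    true_aucs: np.ndarray
    t_multiplier: float

    @property
    def errors(self) -> np.ndarray:
        """Per-run CV estimation error: cv_mean_auc - true_auc."""
        return self.cv_means - self.true_aucs

    @property
    def error_percentiles(self) -> tuple[float, float]:
        """2.5th and 97.5th percentiles of the error distribution."""
        lo, hi = np.percentile(self.errors, [2.5, 97.5])
        return float(lo), float(hi)

    def coverage_with_multiplier(self, m: float) -> float:
        lo = self.cv_means - m * self.cv_sems
        hi = self.cv_means + m * self.cv_sems
        inside = (self.true_aucs >= lo) & (self.true_aucs <= hi)
        return float(inside.mean())

    @property
    def coverage(self) -> float:
        """Fraction of runs whose t(df=k-1) interval contains the truth."""
        return self.coverage_with_multiplier(self.t_multiplier)

    def to_dict(self) -> dict:
        lo, hi = self.error_percentiles
        return {
            "config": asdict(self.config),
            "separation": self.separation,
            "t_multiplier": self.t_multiplier,
            "coverage": self.coverage,
            "coverage_2sem": self.coverage_with_multiplier(2.0),
            "error_percentile_2_5": lo,
            "error_percentile_97_5": hi,
            "mean_true_auc": float(self.true_aucs.mean()),
            "mean_cv_auc": float(self.cv_means.mean()),
            "cv_means": self.cv_means.tolist(),
            "cv_sems": self.cv_sems.tolist(),
            "true_aucs": self.true_aucs.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _cv_mean_sem(
    cfg: CVSimConfig, X: np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> tuple[float, float]:
    """Stratified k-fold CV mean and SEM of held-out fold AUCs."""
    splitter = StratifiedKFold(
        n_splits=cfg.k, shuffle=True, random_state=int(rng.integers(2**31))
    )
    fold_aucs = []
    for train_idx, test_idx in splitter.split(X, y):
        clf = _new_classifier().fit(X[train_idx], y[train_idx])
        scores = clf.decision_function(X[test_idx])
        fold_aucs.append(auc_wmw(ScoreSet(scores=scores, labels=y[test_idx])))
    return mean_sem_across_folds(fold_aucs)


def run_cv_experiment(
    cfg: CVSimConfig, separation: float | None = None
) -> CoverageReport:
    """Run the full coverage experiment.

    Each of ``cfg.runs`` independent runs draws a fresh training set,
    records the trained classifier's AUC on a fresh large test set (the
    truth), and the stratified k-fold CV mean and SEM on the training
    samples.  Folds are stratified by class so no fold is single-class.
    One master seed spawns independent per-run substreams.
    """
    sep = separation if separation is not None else cfg.separation
    if sep is None:
        sep = calibrate_separation(cfg)
    t_mult = float(stats.t.ppf(0.5 + cfg.level / 2.0, df=cfg.k - 1))
    cv_means = np.empty(cfg.runs)
    cv_sems = np.empty(cfg.runs)
    true_aucs = np.empty(cfg.runs)
    streams = np.random.SeedSequence([cfg.seed, 0x5EED]).spawn(cfg.runs)
    for i, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        Xtr, ytr = make_gaussian_dataset(cfg.dim, sep, cfg.n_train, rng)
        clf = _new_classifier().fit(Xtr, ytr)
        Xte, yte = make_gaussian_dataset(cfg.dim, sep, cfg.n_test, rng)
        true_aucs[i] = auc_wmw(
            ScoreSet(scores=clf.decision_function(Xte), labels=yte)
        )
        cv_means[i], cv_sems[i] = _cv_mean_sem(cfg, Xtr, ytr, rng)
    return CoverageReport(
        config=cfg,
        separation=float(sep),
        cv_means=cv_means,
        cv_sems=cv_sems,
        true_aucs=true_aucs,
        t_multiplier=t_mult,
    )
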