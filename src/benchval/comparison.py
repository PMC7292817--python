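"""Model comparison across heterogeneous assays.

A benchmark run yields a grid of AUC values over assays x models x test
folds, with wildly varying assay sizes and active/inactive ratios.  This
module provides the statistics for asking "which model is better?" across
such a grid:

* Cohen's d effect sizes, which weight a performance difference by the
  noise of the measurements rather than its raw magnitude;
* the sign test with Wilson score intervals on the win proportion, which
  treats every comparison unit (test fold, or assay mean) equally and
  answers "on what fraction of problems does model A beat model B?";
* the Wilcoxon signed-rank test, included because its rank weighting can
  let a few large-but-noisy differences outvote many small-but-certain
  ones — the failure mode the sign test avoids;
* win tables (percent of folds on which each model is strictly best) and
  size-stratified win rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .auc import mean_sem_across_folds

__all__ = [
    "BenchmarkTable",
    "ComparisonResult",
    "EffectSize",
    "WilcoxonResult",
    "cohens_d",
    "cohens_d_from_sem",
    "sign_test_wilson",
    "wilcoxon_signed_rank",
    "win_table",
    "size_stratified_wins",
    "load_external_results",
]

TABLE_COLUMNS = ["assay_id", "model", "fold", "auc_roc", "auc_pr", "n_pos", "n_neg"]


@dataclass(frozen=True)
class BenchmarkTable:
    """Assay x model x fold grid of AUC values with fold composition.

    Backed by a DataFrame with columns
    (assay_id, model, fold, auc_roc, auc_pr, n_pos, n_neg); ``auc_pr`` may
    be NaN when unavailable.  Every (assay, model) pair must cover the
    same fold indices, and the fold composition (n_pos, n_neg) must agree
    across models within an assay/fold, since models are evaluated on the
    same test folds.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"benchmark table missing columns: {missing}")
        df = df[TABLE_COLUMNS].reset_index(drop=True)
        for col in ("auc_roc", "auc_pr"):
            vals = df[col].to_numpy(dtype=float)
            ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
            if not ok.all():
                raise ValueError(f"{col} values must lie in [0, 1]")
        if df["auc_roc"].isna().any():
            raise ValueError("auc_roc must be present for every record")
        if df.duplicated(["assay_id", "model", "fold"]).any():
            raise ValueError("duplicate (assay, model, fold) records")
        # complete grid: same folds for every model of an assay
        folds_per = df.groupby(["assay_id", "model"])["fold"].agg(frozenset)
        if folds_per.groupby("assay_id").nunique().gt(1).any():
            raise ValueError("fold indices differ across models within an assay")
        # shared composition across models within an assay/fold
        comp = df.groupby(["assay_id", "fold"])[["n_pos", "n_neg"]].nunique()
        if (comp > 1).any().any():
            raise ValueError("fold composition differs across models")
        object.__setattr__(self, "data", df)

    @property
    def models(self) -> list[str]:
        return sorted(self.data["model"].unique())

    @property
    def assays(self) -> list:
        return sorted(self.data["assay_id"].unique())

    def assay_means(self) -> pd.DataFrame:
        """Per-(assay, model) mean AUC-ROC over folds (arithmetic mean)."""
        return (
            self.data.groupby(["assay_id", "model"])["auc_roc"]
            .mean()
            .unstack("model")
        )

    def assay_sems(self) -> pd.DataFrame:
        """Per-(assay, model) SEM of fold AUCs (population-SD convention)."""
        return (
            self.data.groupby(["assay_id", "model"])["auc_roc"]
            .apply(lambda s: mean_sem_across_folds(s.to_numpy())[1])
            .unstack("model")
        )

    def mean_test_sizes(self) -> pd.Series:
        """Mean test-fold size (n_pos + n_neg) per assay."""
        sizes = self.data.drop_duplicates(["assay_id", "fold"]).copy()
        sizes["n"] = sizes["n_pos"] + sizes["n_neg"]
        return sizes.groupby("assay_id")["n"].mean()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BenchmarkTable":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with the ingredients it was computed from."""

    d: float
    mu1: float
    mu2: float
    s1: float
    s2: float


@dataclass(frozen=True)
class ComparisonResult:
    """Sign-test outcome for one ordered model pair."""

    model_a: str
    model_b: str
    wins_a: int
    wins_b: int
    ties: int
    proportion: float
    wilson_low: float
    wilson_high: float
    level: float
    unit: str

    @property
    def n_units(self) -> int:
        return self.wins_a + self.wins_b + self.ties

    @property
    def significant(self) -> bool:
        """Interval excludes the coin-flip proportion 0.5."""
        return self.wilson_low > 0.5 or self.wilson_high < 0.5

    def to_dict(self) -> dict:
        return {
            "model_a": self.model_a,
            "model_b": self.model_b,
            "wins_a": self.wins_a,
            "wins_b": self.wins_b,
            "ties": self.ties,
            "proportion": self.proportion,
            "wilson_low": self.wilson_low,
            "wilson_high": self.wilson_high,
            "level": self.level,
            "unit": self.unit,
        }


@dataclass(frozen=True)
class WilcoxonResult:
    w: float
    p_value: float
    n_used: int
    mode: str


def cohens_d(mu1: float, mu2: float, s1: float, s2: float) -> EffectSize:
    """Cohen's d: (mu2 - mu1) / sqrt((s1^2 + s2^2) / 2).

    ``s1`` and ``s2`` are standard deviations of the data (fold scores),
    not standard errors of the means; use :func:`cohens_d_from_sem` when
    starting from SEMs.
    """
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if s1 == 0 and s2 == 0:
        raise ValueError("effect size undefined when both spreads are zero")
    d = (mu2 - mu1) / math.sqrt((s1 * s1 + s2 * s2) / 2.0)
    return EffectSize(d=d, mu1=mu1, mu2=mu2, s1=s1, s2=s2)


def cohens_d_from_sem(
    mu1: float, mu2: float, sem1: float, sem2: float, n_folds: int
) -> EffectSize:
    """Cohen's d from per-model SEMs over ``n_folds`` folds (s = sem*sqrt(k))."""
    root_k = math.sqrt(n_folds)
    return cohens_d(mu1, mu2, sem1 * root_k, sem2 * root_k)


def _paired_units(
    table: BenchmarkTable, model_a: str, model_b: str, unit: str
) -> tuple[np.ndarray, np.ndarray]:
    present = set(table.models)
    for m in (model_a, model_b):
        if m not in present:
            raise ValueError(f"model {m!r} not present in the table")
    if unit == "fold":
        wide = table.data.pivot(
            index=["assay_id", "fold"], columns="model", values="auc_roc"
        )
    elif unit == "assay_mean":
        wide = table.assay_means()
    else:
        raise ValueError("unit must be 'fold' or 'assay_mean'")
    return wide[model_a].to_numpy(), wide[model_b].to_numpy()


def sign_test_wilson(
    table: BenchmarkTable,
    model_a: str,
    model_b: str,
    unit: str = "fold",
    level: float = 0.95,
) -> ComparisonResult:
    """Sign test for model_a vs model_b with a Wilson score interval.

    Counts the comparison units (independent test folds, or per-assay mean
    AUCs) on which each model has the higher AUC-ROC.  Exact ties are
    dropped from the denominator and reported separately.  The Wilson
    score interval (no continuity correction) is placed on
    wins_a / (wins_a + wins_b); an interval excluding 0.5 is evidence that
    one model wins more often than a coin flip.
    """
    a, b = _paired_units(table, model_a, model_b, unit)
    wins_a = int((a > b).sum())
    wins_b = int((b > a).sum())
    ties = int((a == b).sum())
    n = wins_a + wins_b
    if n == 0:
        raise ValueError("all comparison units are exact ties")
    low, high = proportion_confint(wins_a, n, alpha=1.0 - level, method="wilson")
    return ComparisonResult(
        model_a=model_a,
        model_b=model_b,
        wins_a=wins_a,
        wins_b=wins_b,
        ties=ties,
        proportion=wins_a / n,
        wilson_low=float(low),
        wilson_high=float(high),
        level=level,
        unit=unit,
    )


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w_plus_doubled: float) -> float:
    """Two-sided exact p for the signed-rank statistic by subset-sum DP.

    Enumerates the null distribution of W+ (sum of ranks with positive
    sign) over all 2^n equally likely sign assignments, with ranks doubled
    to integers so midranks from ties are handled exactly.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in doubled_ranks.astype(int):
        counts[r:] += counts[: total + 1 - r].copy()
    counts /= counts.sum()
    w = int(round(w_plus_doubled))
    hi = max(w, total - w)
    lo = total - hi
    p = counts[hi:].sum() + counts[: lo + 1].sum()
    return float(min(1.0, p))


def wilcoxon_signed_rank(
    differences,
    zero_method: str = "wilcox",
    mode: str = "auto",
    min_n: int = 5,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired performance differences.

    W is the sum of signed ranks: absolute differences are ranked
    (midranks for ties) and each rank takes the sign of its difference.
    Zero differences are dropped before ranking (``zero_method="wilcox"``,
    the original treatment) or kept in the ranking and then dropped from W
    (``"pratt"``).  The two-sided p-value is exact (full enumeration of
    sign assignments) for n <= 25 and a normal approximation with tie
    correction above that; ``mode`` may force ``"exact"`` or ``"approx"``.

    Because W weights differences by the rank of their magnitude, a few
    noisy tasks with big score gaps can dominate many precise tasks with
    small ones.
    """
    diffs = np.asarray(differences, dtype=float)
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError("zero_method must be 'wilcox' or 'pratt'")
    nonzero = diffs != 0
    if not nonzero.any():
        raise ValueError("all differences are zero; test undefined")
    if zero_method == "wilcox":
        diffs = diffs[nonzero]
    n = int((diffs != 0).sum())
    if n < min_n:
        raise ValueError(f"need at least {min_n} non-zero differences")
    ranks = stats.rankdata(np.abs(diffs))
    signed = np.sign(diffs) * ranks
    used = diffs != 0  # under pratt, zeros consumed ranks but contribute 0
    w = float(signed[used].sum())
    r_used = ranks[used]
    if mode == "auto":
        mode = "exact" if n <= 25 else "approx"
    if mode == "exact":
        w_plus = signed[used][signed[used] > 0].sum()
        p = _exact_signed_rank_p(2.0 * r_used, 2.0 * w_plus)
    elif mode == "approx":
        # var(W) = sum of squared used ranks (ranks independent +/-1 signs)
        var_w = float((r_used**2).sum())
        z = w / math.sqrt(var_w)
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("mode must be 'auto', 'exact', or 'approx'")
    return WilcoxonResult(w=w, p_value=p, n_used=n, mode=mode)


def win_table(table: BenchmarkTable) -> pd.Series:
    """Percent of test folds on which each model is strictly best.

    A fold where the maximum AUC-ROC is shared counts once in the ``Tie``
    bucket; percentages sum to 100.
    """
    models = table.models
    if len(models) < 2:
        raise ValueError("need at least two models")
    wide = table.data.pivot(
        index=["assay_id", "fold"], columns="model", values="auc_roc"
    )
    vals = wide.to_numpy()
    best = vals.max(axis=1, keepdims=True)
    is_best = vals == best
    tie_mask = is_best.sum(axis=1) > 1
    out = {}
    for j, m in enumerate(wide.columns):
        out[m] = float((is_best[:, j] & ~tie_mask).mean() * 100.0)
    out["Tie"] = float(tie_mask.mean() * 100.0)
    return pd.Series(out)


def size_stratified_wins(
    table: BenchmarkTable,
    model_a: str,
    model_b: str,
    min_test_size: float = 0.0,
) -> tuple[float, int]:
    """Win proportion of model_a over model_b among large assays.

    Qualifying assays are those whose mean test-fold size exceeds
    ``min_test_size``; comparison is on per-assay mean AUC-ROC with exact
    ties dropped.  Returns (proportion, number of qualifying assays).
    """
    if min_test_size < 0:
        raise ValueError("min_test_size must be non-negative")
    sizes = table.mean_test_sizes()
    qualifying = sizes[sizes > min_test_size].index
    if len(qualifying) == 0:
        raise ValueError(
            f"no assays with mean test size above {min_test_size}"
        )
    means = table.assay_means().loc[qualifying]
    a = means[model_a].to_numpy()
    b = means[model_b].to_numpy()
    wins_a = int((a > b).sum())
    wins_b = int((b > a).sum())
    if wins_a + wins_b == 0:
        raise ValueError("all qualifying assays are exact ties")
    return wins_a / (wins_a + wins_b), len(qualifying)


def load_external_results(
    auc_file, composition_file=None, model: str = "model", metric: str = "auc_roc"
) -> BenchmarkTable:
    """Map externally published per-fold AUC files into a BenchmarkTable.

    Intended for the publicly released large-scale ChEMBL bioactivity
    benchmark results (github.com/ml-jku), which ship per-method files of
    fold-level AUC values indexed by assay.  Expects delimited text with
    columns (assay_id, fold, auc) and an optional composition file with
    (assay_id, fold, n_pos, n_neg).  This loader needs the external
    download and is therefore exercised only manually, never in CI.
    """
    auc = pd.read_csv(auc_file)
    auc = auc.rename(columns={auc.columns[2]: metric})
    auc["model"] = model
    if composition_file is not None:
        comp = pd.read_csv(composition_file)
        auc = auc.merge(comp, on=["assay_id", "fold"], how="left")
    else:
        auc["n_pos"] = np.nan
        auc["n_neg"] = np.nan
    if "auc_pr" not in auc.columns:
        auc["auc_pr"] = np.nan
    if "auc_roc" not in auc.columns:
        auc["auc_roc"] = np.nan
    return BenchmarkTable(auc[TABLE_COLUMNS])
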