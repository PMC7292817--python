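"""Synthetic classifier-benchmark tables with realistic small-sample structure.

Generates assay x model x fold grids of AUC values emulating the statistical
shape of large public ChEMBL bioactivity benchmarks: assay sizes spanning
roughly 100 to 30,000 compounds (log-uniform), threefold splits of unequal
size (Dirichlet partition), highly variable active fractions including an
inverted-skew component (folds with >= 90% actives, the opposite of a real
screen's hit rate), and multiple models whose relative performance varies
by assay and with assay size.

Fold AUCs are never "latent AUC plus Gaussian noise": each fold's AUC is
computed by actually sampling scores from a binormal model at the latent
AUC and running the WMW statistic, so small folds show the discreteness,
bounded support, and skew that real fold AUCs have.  The latent parameters
are returned as ground truth for parameter-recovery and calibration tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .auc import ScoreSet, auc_wmw
from .comparison import TABLE_COLUMNS, BenchmarkTable
from .metric_sim import binormal_scores

__all__ = [
    "BenchmarkGenConfig",
    "GeneratedBenchmark",
    "generate_benchmark",
    "inject_degenerate_folds",
    "paradox_benchmark",
]


@dataclass(frozen=True)
class BenchmarkGenConfig:
    """Knobs of the synthetic benchmark generator.

    Latent fold AUCs live on the probit scale: an assay draws a random
    effect around ``base_auc``; each model adds its ``model_effects``
    offset; optional advantage mechanisms plant known win structure.

    * ``advantage_prob``/``advantage_delta``: with two models, each assay
      independently favors the first model with this probability; the
      favored model gets +delta (probit) on that assay.  Makes per-assay
      win probabilities known by construction.
    * ``fold_favorite_probs``: per-fold favored model drawn with these
      probabilities; the favorite gets +``advantage_delta``.  Plants known
      best-model frequencies for win tables.
    * ``size_slope``: probit advantage of the first model per decade of
      assay size relative to 1,000 compounds, for size-dependent effects.
    * ``inverted_skew_prob``: probability an assay gets one inverted-skew
      fold (>= 90% actives); other folds draw their active fraction from
      ``active_fraction_beta`` (default Beta(2, 5), mean ~0.29).
    """

    n_assays: int = 100
    model_names: tuple[str, ...] = ("FNN", "SVM")
    n_folds: int = 3
    size_range: tuple[int, int] = (100, 30_000)
    fold_alpha: float = 4.0
    active_fraction_beta: tuple[float, float] = (2.0, 5.0)
    inverted_skew_prob: float = 0.126
    base_auc: float = 0.8
    assay_sd: float = 0.35
    model_effects: tuple[float, ...] | None = None
    advantage_prob: float | None = None
    advantage_delta: float = 0.0
    fold_favorite_probs: tuple[float, ...] | None = None
    size_slope: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_assays < 1 or self.n_folds < 1:
            raise ValueError("need at least one assay and one fold")
        if len(self.model_names) < 1:
            raise ValueError("need at least one model")
        lo, hi = self.size_range
        if not 3 * self.n_folds <= lo <= hi:
            raise ValueError("size_range must allow >= 3 compounds per fold")
        if self.model_effects is not None and len(self.model_effects) != len(
            self.model_names
        ):
            raise ValueError("model_effects must match model_names")
        if self.advantage_prob is not None and len(self.model_names) != 2:
            raise ValueError("advantage_prob requires exactly two models")
        if self.fold_favorite_probs is not None and len(
            self.fold_favorite_probs
        ) != len(self.model_names):
            raise ValueError("fold_favorite_probs must match model_names")


@dataclass(frozen=True)
class GeneratedBenchmark:
    """A generated table plus the latent ground truth that produced it."""

    table: BenchmarkTable
    latent_auc: pd.DataFrame  # index (assay_id, model, fold), latent true AUC
    favored: pd.Series | None  # per-assay or per-fold favored model, if planted


def _average_precision(fold: ScoreSet) -> float:
    """Average precision (step-function AUC-PR), tie-aware.

    Lightweight equivalent of sklearn's average_precision_score (asserted
    identical in the test suite); the generator calls it per fold, where
    sklearn's input re-validation overhead would dominate the runtime.
    """
    order = np.argsort(-fold.scores, kind="stable")
    y = fold.labels[order].astype(float)
    s = fold.scores[order]
    # threshold groups end at the last index of each distinct score
    idx = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[idx]
    precision = tp / (idx + 1.0)
    recall_steps = np.diff(np.r_[0.0, tp]) / tp[-1]
    return float(min(1.0, np.sum(recall_steps * precision)))


def _latent_to_auc(z: np.ndarray) -> np.ndarray:
    # keep strictly inside (0,1) so binormal sampling stays defined
    return np.clip(stats.norm.cdf(z), 1e-4, 1.0 - 1e-4)


def _fold_compositions(
    cfg: BenchmarkGenConfig, size: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Unequal fold sizes by Dirichlet partition; per-fold active counts."""
    weights = rng.dirichlet([cfg.fold_alpha] * cfg.n_folds)
    sizes = np.maximum(3, np.round(weights * size).astype(int))
    a, b = cfg.active_fraction_beta
    fracs = rng.beta(a, b, size=cfg.n_folds)
    if rng.random() < cfg.inverted_skew_prob:
        fracs[rng.integers(cfg.n_folds)] = rng.uniform(0.90, 0.97)
    comps = []
    for ns, f in zip(sizes, fracs):
        n_pos = int(np.clip(round(f * ns), 1, ns - 1))
        comps.append((n_pos, int(ns - n_pos)))
    return comps


def generate_benchmark(cfg: BenchmarkGenConfig) -> GeneratedBenchmark:
    """Generate a benchmark table under the configured latent model."""
    rng = np.random.default_rng(cfg.seed)
    n_models = len(cfg.model_names)
    effects = np.asarray(cfg.model_effects or np.zeros(n_models), dtype=float)
    z_base = stats.norm.ppf(cfg.base_auc)
    lo, hi = cfg.size_range

    records = []
    latent_rows = []
    favored_rows = {}
    for a_idx in range(cfg.n_assays):
        assay_id = f"assay_{a_idx:04d}"
        size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        comps = _fold_compositions(cfg, size, rng)
        z_assay = z_base + rng.normal(0.0, cfg.assay_sd)
        size_adv = cfg.size_slope * math.log10(size / 1000.0)

        assay_adv = np.zeros(n_models)
        if cfg.advantage_prob is not None:
            fav = 0 if rng.random() < cfg.advantage_prob else 1
            assay_adv[fav] = cfg.advantage_delta
            favored_rows[assay_id] = cfg.model_names[fav]

        for fold_idx, (n_pos, n_neg) in enumerate(comps):
            fold_adv = np.zeros(n_models)
            if cfg.fold_favorite_probs is not None:
                fav = rng.choice(n_models, p=cfg.fold_favorite_probs)
                fold_adv[fav] = cfg.advantage_delta
                favored_rows[(assay_id, fold_idx)] = cfg.model_names[fav]
            for m_idx, model in enumerate(cfg.model_names):
                z = z_assay + effects[m_idx] + assay_adv[m_idx] + fold_adv[m_idx]
                if m_idx == 0:
                    z += size_adv
                latent = float(_latent_to_auc(np.array(z))[()])
                fold = binormal_scores(n_pos, n_neg, latent, rng)
                records.append(
                    {
                        "assay_id": assay_id,
                        "model": model,
                        "fold": fold_idx,
                        "auc_roc": auc_wmw(fold),
                        "auc_pr": _average_precision(fold),
                        "n_pos": n_pos,
                        "n_neg": n_neg,
                    }
                )
                latent_rows.append(
                    {
                        "assay_id": assay_id,
                        "model": model,
                        "fold": fold_idx,
                        "latent_auc": latent,
                    }
                )
    table = BenchmarkTable(pd.DataFrame.from_records(records, columns=TABLE_COLUMNS))
    latent = pd.DataFrame.from_records(latent_rows).set_index(
        ["assay_id", "model", "fold"]
    )["latent_auc"]
    favored = pd.Series(favored_rows) if favored_rows else None
    return GeneratedBenchmark(table=table, latent_auc=latent, favored=favored)


def inject_degenerate_folds(
    table: BenchmarkTable,
    fraction: float,
    seed: int = 0,
    composition: tuple[int, int] = (2, 1),
) -> BenchmarkTable:
    """Replace a fraction of folds with tiny degenerate compositions.

    Selected (assay, fold) cells are re-simulated at the given tiny
    composition (default 2 actives / 1 inactive, whose AUC can only be
    0, 0.5, or 1) so downstream code must exercise the enumeration and
    simulation interval paths.  Scores are resampled at a neutral latent
    AUC of 0.5, i.e. the degenerate folds carry no signal.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0.0:
        return table
    rng = np.random.default_rng(seed)
    df = table.data.copy()
    cells = df[["assay_id", "fold"]].drop_duplicates().to_numpy()
    n_replace = int(round(fraction * len(cells)))
    picked = rng.choice(len(cells), size=n_replace, replace=False)
    n_pos, n_neg = composition
    for i in picked:
        assay_id, fold = cells[i]
        mask = (df["assay_id"] == assay_id) & (df["fold"] == fold)
        for row in df.index[mask]:
            fold_scores = binormal_scores(n_pos, n_neg, 0.5, rng)
            df.loc[row, ["auc_roc", "auc_pr", "n_pos", "n_neg"]] = (
                auc_wmw(fold_scores),
                _average_precision(fold_scores),
                n_pos,
                n_neg,
            )
    return BenchmarkTable(df)


def paradox_benchmark(
    seed: int = 0,
    n_small: int = 10,
    n_large: int = 12,
    small_size: int = 30,
    large_size: int = 6000,
) -> GeneratedBenchmark:
    """A fixture where rank-based and uncertainty-aware evidence disagree.

    Tiny, noisy assays favor model A by a large raw margin, while large,
    precise assays favor model B by a small but real one.  Because the
    signed-rank statistic W ranks differences by raw magnitude, the noisy
    assays claim the top ranks and push W toward A, even though per-assay
    effect sizes (which weight by measurement noise) and the large-assay
    win rate point decisively at B.  The flip requires the noisy group to
    out-rank the precise group, so the counts are comparable rather than
    "few vs many".  Constructed, not universal: it demonstrates the
    failure mode on demand.
    """
    rng = np.random.default_rng(seed)
    records = []
    latent_rows = []

    def add_assay(assay_id, size, latents):
        comps = []
        weights = rng.dirichlet([8.0, 8.0, 8.0])
        for w in weights:
            ns = max(4, int(round(w * size)))
            n_pos = max(1, min(ns - 1, int(round(0.3 * ns))))
            comps.append((n_pos, ns - n_pos))
        for fold_idx, (n_pos, n_neg) in enumerate(comps):
            for model, latent in latents.items():
                fold = binormal_scores(n_pos, n_neg, latent, rng)
                records.append(
                    {
                        "assay_id": assay_id,
                        "model": model,
                        "fold": fold_idx,
                        "auc_roc": auc_wmw(fold),
                        "auc_pr": np.nan,
                        "n_pos": n_pos,
                        "n_neg": n_neg,
                    }
                )
                latent_rows.append(
                    {
                        "assay_id": assay_id,
                        "model": model,
                        "fold": fold_idx,
                        "latent_auc": latent,
                    }
                )

    # tiny noisy assays: big raw advantage for model A
    for i in range(n_small):
        add_assay(f"small_{i:02d}", small_size, {"A": 0.95, "B": 0.55})
    # large precise assays: small but real advantage for model B
    for i in range(n_large):
        add_assay(f"large_{i:02d}", large_size, {"A": 0.880, "B": 0.895})
    table = BenchmarkTable(pd.DataFrame.from_records(records, columns=TABLE_COLUMNS))
    latent = pd.DataFrame.from_records(latent_rows).set_index(
        ["assay_id", "model", "fold"]
    )["latent_auc"]
    return GeneratedBenchmark(table=table, latent_auc=latent, favored=None)
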