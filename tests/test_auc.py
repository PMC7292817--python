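"""Single-fold AUC estimation and uncertainty."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from benchval import (
    AUCEstimate,
    DegenerateFoldError,
    ScoreSet,
    UndefinedAUCError,
    auc_wmw,
    enumerate_auc_distribution,
    hanley_mcneil_ci,
    mean_ci_t2,
    mean_sem_across_folds,
    read_scores,
    simulate_degenerate_ci,
)


def brute_force_auc(pos, neg):
    """All-pairs oracle: correct pairs + half credit for ties."""
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestAucWmw:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([0.9, 0.8], [0.1], 1.0),  # perfect separation
            ([0.1, 0.2], [0.9], 0.0),  # perfect inversion
            ([0.5, 0.9], [0.5], 0.75),  # one correct pair + one tied pair
        ],
    )
    def test_known_folds(self, pos, neg, expected):
        assert auc_wmw(ScoreSet.from_pos_neg(pos, neg)) == expected

    def test_single_class_fold_is_an_error(self):
        with pytest.raises(UndefinedAUCError):
            auc_wmw(ScoreSet.from_pos_neg([0.3, 0.4], []))
        with pytest.raises(UndefinedAUCError):
            auc_wmw(ScoreSet.from_pos_neg([], [0.3]))

    @given(st.data())
    def test_agrees_with_pair_counting_oracle(self, data):
        """Midrank formula equals brute-force pair counting, ties included."""
        n_pos = data.draw(st.integers(1, 25))
        n_neg = data.draw(st.integers(1, 25))
        # coarse grid of score values induces plenty of ties
        score = st.sampled_from([0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0])
        pos = data.draw(st.lists(score, min_size=n_pos, max_size=n_pos))
        neg = data.draw(st.lists(score, min_size=n_neg, max_size=n_neg))
        fold = ScoreSet.from_pos_neg(pos, neg)
        assert auc_wmw(fold) == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_score_negation_complements_auc(self, rng):
        scores = rng.permutation(np.linspace(0, 1, 30))  # tie-free
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]  # both classes present
        fold = ScoreSet(scores=scores, labels=labels)
        flipped = ScoreSet(scores=-scores, labels=labels)
        assert auc_wmw(fold) + auc_wmw(flipped) == pytest.approx(1.0)

    def test_matches_sklearn_reference(self, rng):
        """Independent cross-check against sklearn's ROC-AUC."""
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            labels = rng.integers(0, 2, 40)
            labels[:2] = [0, 1]
            scores = np.round(rng.random(40), 2)
            fold = ScoreSet(scores=scores, labels=labels)
            assert auc_wmw(fold) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestHanleyMcneil:
    def test_large_fold_interval_to_three_decimals(self):
        est = hanley_mcneil_ci(0.889, 5553, 13855, level=0.95)
        assert (round(est.ci_low, 3), round(est.ci_high, 3)) == (0.883, 0.895)
        assert est.method == "hanley_mcneil"

    def test_perfect_discrimination_has_zero_width(self):
        est = hanley_mcneil_ci(1.0, 10, 10)
        assert est.se == 0.0
        assert (est.ci_low, est.ci_high) == (1.0, 1.0)

    def test_balanced_small_fold_formula_value(self):
        # direct evaluation of the closed form at AUC 0.69, 18/18
        est = hanley_mcneil_ci(0.69, 18, 18)
        assert est.ci_low == pytest.approx(0.516, abs=5e-4)
        assert est.ci_high == pytest.approx(0.864, abs=5e-4)

    def test_degenerate_fold_raises_with_guidance(self):
        with pytest.raises(DegenerateFoldError, match="degrees of freedom"):
            hanley_mcneil_ci(0.62, 1, 29)

    @pytest.mark.parametrize("auc", [0.6, 0.75, 0.9])
    def test_width_non_increasing_in_class_counts(self, auc):
        widths = [
            hanley_mcneil_ci(auc, n, 50).ci_high - hanley_mcneil_ci(auc, n, 50).ci_low
            for n in (5, 20, 80, 320)
        ]
        assert all(a >= b for a, b in zip(widths, widths[1:]))
        widths = [
            hanley_mcneil_ci(auc, 50, n).ci_high - hanley_mcneil_ci(auc, 50, n).ci_low
            for n in (5, 20, 80, 320)
        ]
        assert all(a >= b for a, b in zip(widths, widths[1:]))

    @given(
        auc=st.floats(0.0, 1.0),
        n_pos=st.integers(2, 5000),
        n_neg=st.integers(2, 5000),
    )
    def test_interval_stays_in_unit_range(self, auc, n_pos, n_neg):
        est = hanley_mcneil_ci(auc, n_pos, n_neg)
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0


class TestEnumeration:
    def test_two_actives_one_inactive(self):
        dist = enumerate_auc_distribution(2, 1)
        assert list(dist.values) == [0.0, 0.5, 1.0]
        assert np.allclose(dist.probabilities, 1 / 3)
        assert dist.mean == pytest.approx(0.5)
        assert round(dist.sd, 2) == 0.41

    def test_single_pair(self):
        dist = enumerate_auc_distribution(1, 1)
        assert list(dist.values) == [0.0, 1.0]
        assert dist.mean == pytest.approx(0.5)
        assert dist.sd == pytest.approx(0.5)

    def test_two_by_two(self):
        dist = enumerate_auc_distribution(2, 2)
        assert list(dist.values) == [0.0, 0.25, 0.5, 0.75, 1.0]
        assert np.allclose(dist.probabilities, np.array([1, 1, 2, 1, 1]) / 6)
        assert dist.sd == pytest.approx(0.3227, abs=5e-4)

    @pytest.mark.parametrize(
        "n_pos, n_neg",
        [(a, b) for a in range(1, 7) for b in range(1, 7) if a + b <= 12],
    )
    def test_mean_half_and_probabilities_sum(self, n_pos, n_neg):
        dist = enumerate_auc_distribution(n_pos, n_neg)
        assert dist.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
        assert dist.mean == pytest.approx(0.5, abs=1e-12)
        assert ((dist.values >= 0) & (dist.values <= 1)).all()

    @pytest.mark.parametrize("n_pos, n_neg", [(2, 3), (4, 4), (3, 6)])
    def test_against_monte_carlo_oracle(self, n_pos, n_neg, rng):
        """Random-ranking simulation reproduces the exact mean and sd."""
        dist = enumerate_auc_distribution(n_pos, n_neg)
        n = n_pos + n_neg
        reps = 100_000
        picks = np.argsort(rng.random((reps, n)), axis=1)[:, :n_pos]
        ranks = np.arange(1, n + 1, dtype=float)
        aucs = (ranks[picks].sum(axis=1) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        mc_se = aucs.std() / np.sqrt(reps)
        assert abs(aucs.mean() - dist.mean) < 3 * mc_se

    def test_cap_guard_recommends_monte_carlo(self):
        with pytest.raises(ValueError, match="Monte Carlo"):
            enumerate_auc_distribution(15, 15)


class TestDegenerateSimulation:
    def test_perfectly_separated_singleton_upper_bound(self):
        fold = ScoreSet.from_pos_neg([5.0], [0.0] * 29)
        est = simulate_degenerate_ci(fold, seed=7)
        assert est.ci_high == 1.0
        assert est.method == "simulation"

    def test_seeded_reproducibility(self, rng):
        fold = ScoreSet.from_pos_neg(rng.random(1), rng.random(29))
        a = simulate_degenerate_ci(fold, seed=11)
        b = simulate_degenerate_ci(fold, seed=11)
        assert a == b

    def test_singleton_fold_interval_spans_most_of_unit_range(self, rng):
        fold = ScoreSet.from_pos_neg(rng.random(1), rng.random(29))
        est = simulate_degenerate_ci(fold, seed=3)
        assert est.ci_high - est.ci_low > 0.8

    def test_permutation_quantiles_match_exact_enumeration(self, rng):
        """Dual route: the simulated distribution is the enumerable one."""
        fold = ScoreSet.from_pos_neg(rng.random(2), rng.random(3))
        est = simulate_degenerate_ci(fold, level=0.7, reps=50_000, seed=5)
        dist = enumerate_auc_distribution(2, 3)
        # exact 15% / 85% quantiles of the discrete enumeration, both of
        # which sit strictly inside a probability atom (no boundary effects)
        cdf = np.cumsum(dist.probabilities)
        lo = dist.values[np.searchsorted(cdf, 0.15)]
        hi = dist.values[np.searchsorted(cdf, 0.85)]
        assert est.ci_low == pytest.approx(lo, abs=0.05)
        assert est.ci_high == pytest.approx(hi, abs=0.05)

    def test_bootstrap_variant_tracks_the_observed_scores(self, rng):
        pos = rng.normal(2.0, 0.3, 8)
        neg = rng.normal(0.0, 0.3, 8)
        fold = ScoreSet.from_pos_neg(pos, neg)
        est = simulate_degenerate_ci(fold, seed=2, method="bootstrap")
        # well-separated scores: bootstrap interval concentrates near 1
        assert est.ci_low > 0.5

    def test_empty_class_is_an_error(self):
        fold = ScoreSet.from_pos_neg([0.5], [])
        with pytest.raises(UndefinedAUCError):
            simulate_degenerate_ci(fold, seed=1)


class TestFoldAggregation:
    def test_mean_and_sem_population_convention(self):
        mean, sem = mean_sem_across_folds([0.38, 0.97, 0.68])
        assert mean == pytest.approx(0.67, abs=0.01)
        assert sem == pytest.approx(0.14, abs=0.005)

    def test_constant_folds_have_zero_sem(self):
        mean, sem = mean_sem_across_folds([0.8, 0.8, 0.8])
        assert mean == pytest.approx(0.8)
        assert sem == pytest.approx(0.0, abs=1e-12)

    def test_three_fold_small_assay_cell(self):
        mean, sem = mean_sem_across_folds([0.44, 0.62, 0.64])
        assert mean == pytest.approx(0.57, abs=0.01)
        assert sem == pytest.approx(0.05, abs=0.005)

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            mean_sem_across_folds([0.5])

    def test_t2_interval_halfwidth(self):
        mean, sem = mean_sem_across_folds([0.44, 0.62, 0.64])
        lo, hi = mean_ci_t2([0.44, 0.62, 0.64])
        assert (lo + hi) / 2 == pytest.approx(mean)
        assert (hi - lo) / 2 == pytest.approx(4.303 * sem, abs=1e-3)

    def test_t2_interval_degenerate_and_symmetric_cases(self):
        lo0, hi0 = mean_ci_t2([0.7, 0.7, 0.7])
        assert lo0 == pytest.approx(0.7) and hi0 == pytest.approx(0.7)
        lo, hi = mean_ci_t2([0.4, 0.5, 0.6])
        assert lo + hi == pytest.approx(1.0)

    def test_t2_requires_exactly_three_folds(self):
        with pytest.raises(ValueError):
            mean_ci_t2([0.5, 0.6])


class TestScoreIO:
    def test_round_trip_scores_file(self, tmp_path, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        path = tmp_path / "fold.tsv"
        np.savetxt(path, np.column_stack([scores, labels]))
        fold = read_scores(path)
        assert np.allclose(fold.scores, scores)
        assert (fold.labels == labels).all()
        assert auc_wmw(fold) == auc_wmw(ScoreSet(scores=scores, labels=labels))

    def test_estimate_serialization_records_method(self):
        est = hanley_mcneil_ci(0.75, 30, 60)
        d = est.to_dict()
        assert d["method"] == "hanley_mcneil"
        assert d["ci_low"] <= d["auc"] <= d["ci_high"]

    def test_invalid_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            ScoreSet(scores=np.array([0.1, 0.2]), labels=np.array([1, 2]))
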