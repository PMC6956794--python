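"""Pair-level splitting, PR/ROC metrics with class-prior adjustment,
alpha cross-validation, and bootstrap comparison."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from cocomine.data_model import Comention
from cocomine.evaluation import (
    adjusted_precision,
    auprc,
    auroc,
    bootstrap_compare,
    cv_alpha,
    downsample_train,
    evaluate_pairs,
    pair_labels,
    pr_curve,
    split_pairs,
)

from conftest import make_pair


def pairset(n):
    return [make_pair(i, i + 1) for i in range(n)]


class TestSplitPairs:
    def test_fraction_arithmetic(self):
        train, test = split_pairs(pairset(10), 0.2, seed=1)
        assert len(test) == 2 and len(train) == 8

    def test_partition_property(self):
        pairs = pairset(23)
        train, test = split_pairs(pairs, 0.2, seed=5)
        assert train | test == set(pairs)
        assert not train & test

    def test_deterministic_per_seed(self):
        pairs = pairset(30)
        assert split_pairs(pairs, 0.3, seed=9) == split_pairs(pairs, 0.3, seed=9)
        assert split_pairs(pairs, 0.3, seed=9) != split_pairs(pairs, 0.3, seed=10)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_bad_fraction(self, frac):
        with pytest.raises(ValueError):
            split_pairs(pairset(5), frac)


class TestDownsample:
    def _records(self, counts):
        out = []
        for k, (i, n) in enumerate(counts.items()):
            p = make_pair(i, i)
            out.extend(
                Comention(f"d{k}_{s}", s % 7, p, "DISEASE_ x GENE_ .") for s in range(n)
            )
        return out

    def test_small_pairs_kept_intact(self):
        records = self._records({1: 5})
        assert downsample_train(records, 100, seed=0) == records

    def test_large_pairs_capped_exactly(self):
        records = self._records({1: 250})
        kept = downsample_train(records, 100, seed=0)
        assert len(kept) == 100
        assert set(kept) <= set(records)

    def test_kept_counts_equal_min_n_max_per_pair(self, rng):
        sizes = {i: int(rng.integers(1, 40)) for i in range(8)}
        records = self._records(sizes)
        kept = downsample_train(records, 12, seed=3)
        per_pair = {}
        for r in kept:
            per_pair[r.pair] = per_pair.get(r.pair, 0) + 1
        for i, n in sizes.items():
            assert per_pair[make_pair(i, i)] == min(n, 12)

    def test_bad_max(self):
        with pytest.raises(ValueError):
            downsample_train([], 0)


def scores_labels(items):
    """items: list of (score, is_positive) -> (scores dict, labels dict)."""
    scores, labels = {}, {}
    for k, (s, y) in enumerate(items):
        p = make_pair(k, k)
        scores[p], labels[p] = s, y
    return scores, labels


class TestPRCurve:
    def test_hand_enumerated_four_pairs(self):
        scores, labels = scores_labels([(0.9, True), (0.8, False), (0.7, True), (0.1, False)])
        c = pr_curve(scores, labels)
        assert np.allclose(c.thresholds, [0.9, 0.8, 0.7, 0.1])
        assert np.allclose(c.precision, [1, 1 / 2, 2 / 3, 1 / 2])
        assert np.allclose(c.recall, [1 / 2, 1 / 2, 1, 1])
        assert auprc(c) == pytest.approx(5 / 6, rel=1e-12)

    def test_perfect_separation_reaches_precision_one_at_full_recall(self):
        scores, labels = scores_labels([(0.9, True), (0.8, True), (0.2, False)])
        c = pr_curve(scores, labels)
        assert c.precision[c.recall == 1.0].max() == 1.0
        assert auprc(c) == 1.0

    def test_all_scores_tied_single_point(self):
        scores, labels = scores_labels([(0.5, True), (0.5, False), (0.5, False), (0.5, True)])
        c = pr_curve(scores, labels)
        assert len(c.thresholds) == 1
        assert c.precision[0] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        scores, labels = scores_labels([(0.9, True), (0.1, True)])
        with pytest.raises(ValueError):
            pr_curve(scores, labels)

    def test_tp_plus_fn_constant(self, rng):
        items = [(float(rng.random()), bool(rng.random() < 0.3)) for _ in range(50)]
        items[0], items[1] = (0.5, True), (0.5, False)
        scores, labels = scores_labels(items)
        c = pr_curve(scores, labels)
        assert np.allclose(c.tp + c.fn, sum(y for _, y in items))

    def test_unscored_pairs_count_as_score_zero(self):
        scores, labels = scores_labels([(0.9, True), (0.2, False)])
        extra = make_pair(99, 99)
        labels[extra] = True  # gold pair never scored
        c = pr_curve(scores, labels)
        assert c.tp[-1] == 2  # recovered only at the zero threshold


class TestAdjustedPrecision:
    def test_equal_priors_reduce_to_precision(self):
        assert adjusted_precision(7, 3, 0.4, 0.4) == pytest.approx(0.7)

    def test_no_false_positives_gives_one(self):
        assert adjusted_precision(5, 0, 0.1, 0.7) == 1.0

    def test_hand_arithmetic(self):
        # TP=FP, a=0.1, b=0.5 -> 0.2/(0.2+1.8) = 0.1
        assert adjusted_precision(10, 10, 0.1, 0.5) == pytest.approx(0.1, rel=1e-12)

    @pytest.mark.parametrize("a,b", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0), (0.5, 1.0)])
    def test_degenerate_priors_rejected(self, a, b):
        with pytest.raises(ValueError):
            adjusted_precision(1, 1, a, b)


class TestAUPRC:
    def test_adjusted_equals_unadjusted_when_a_is_b(self, rng):
        items = [(float(rng.random()), bool(rng.random() < 0.4)) for _ in range(80)]
        items[:2] = [(0.5, True), (0.5, False)]
        scores, labels = scores_labels(items)
        b = np.mean([y for _, y in items])
        c = pr_curve(scores, labels, a=float(b))
        assert auprc(c, adjusted=True) == pytest.approx(auprc(c), rel=1e-12)

    def test_perfect_classifier_is_one_adjusted_or_not(self):
        items = [(0.9, True)] * 3 + [(0.1, False)] * 27
        scores, labels = scores_labels(items)
        c = pr_curve(scores, labels, a=0.1)
        assert auprc(c) == 1.0 and auprc(c, adjusted=True) == 1.0

    def test_monotone_transform_invariance(self, rng):
        items = [(float(rng.random()), bool(rng.random() < 0.3)) for _ in range(60)]
        items[:2] = [(0.5, True), (0.5, False)]
        scores, labels = scores_labels(items)
        squashed = {p: np.tanh(3 * s) for p, s in scores.items()}  # strictly monotone
        c1, c2 = pr_curve(scores, labels), pr_curve(squashed, labels)
        assert auprc(c1, adjusted=True) == pytest.approx(auprc(c2, adjusted=True), rel=1e-12)
        assert auroc(scores, labels) == pytest.approx(auroc(squashed, labels), rel=1e-12)

    def test_matches_sklearn_average_precision(self, rng):
        for _ in range(10):
            y = rng.random(120) < 0.25
            if y.all() or not y.any():
                continue
            s = np.round(rng.random(120), 2)  # induce ties
            scores, labels = scores_labels(list(zip(s, y)))
            c = pr_curve(scores, labels)
            assert auprc(c) == pytest.approx(
                average_precision_score(y, s), rel=1e-12
            )


class TestAUROC:
    def test_perfect(self):
        s, l = scores_labels([(0.9, True), (0.8, True), (0.2, False)])
        assert auroc(s, l) == 1.0

    def test_all_tied_is_half(self):
        s, l = scores_labels([(0.5, True), (0.5, False), (0.5, True), (0.5, False)])
        assert auroc(s, l) == 0.5

    def test_one_inversion_two_by_two(self):
        s, l = scores_labels([(0.9, True), (0.7, False), (0.8, True), (0.6, False)])
        # swap one pos below one neg
        s2, l2 = scores_labels([(0.9, True), (0.8, False), (0.7, True), (0.1, False)])
        assert auroc(s2, l2) == pytest.approx(0.75)

    def test_matches_sklearn(self, rng):
        y = rng.random(150) < 0.4
        y[:2] = [True, False]
        s = np.round(rng.random(150), 2)
        scores, labels = scores_labels(list(zip(s, y)))
        assert auroc(scores, labels) == pytest.approx(roc_auc_score(y, s), rel=1e-12)


class TestEvaluatePairs:
    def test_result_fields_in_range(self, rng):
        items = [(float(rng.random()), bool(rng.random() < 0.3)) for _ in range(40)]
        items[:2] = [(0.5, True), (0.5, False)]
        scores, labels = scores_labels(items)
        res = evaluate_pairs(scores, labels)
        assert 0 <= res.auprc <= 1 and 0 <= res.adjusted_auprc <= 1 and 0 <= res.auroc <= 1
        assert res.n_pairs == 40


class TestCVAlpha:
    def _labeled_corpus(self, seed):
        from cocomine import GeneratorConfig, generate_corpus, generate_world, label_comentions

        cfg = GeneratorConfig(
            seed=seed, n_documents=700, n_gold_positive=80,
            n_entities={"disease": 12, "gene": 12}, n_grey=3, vocab_size=300,
        )
        world = generate_world(cfg)
        labeled, _ = label_comentions(generate_corpus(world, cfg), world[0])
        return labeled

    def test_single_value_grid_returned(self):
        from cocomine.sentence_model import Hyperparams

        labeled = self._labeled_corpus(0)
        hp = Hyperparams(dim=8, epochs=5, learning_rate=0.05, n_buckets=500, seed=0)
        best, perf = cv_alpha(labeled, folds=3, alpha_grid=[0.4], seed=0, hp=hp)
        assert best == 0.4 and set(perf) == {0.4}

    def test_too_few_pairs_rejected(self):
        records = [
            Comention("d1", 0, make_pair(1, 1), "t .", label="positive"),
            Comention("d2", 0, make_pair(1, 1), "t .", label="positive"),
        ]
        with pytest.raises(ValueError):
            cv_alpha(records, folds=3, alpha_grid=[0.5], seed=0)

    def test_context_alpha_not_below_baseline_alpha(self):
        """Directionally, the context-aware model tolerates at least as much
        weight on raw counts as the count baseline (sign test, 5 seeds)."""
        from cocomine.sentence_model import Hyperparams

        grid = [round(0.1 * k, 1) for k in range(11)]
        wins = 0
        for seed in range(5):
            labeled = self._labeled_corpus(seed)
            hp = Hyperparams(dim=16, epochs=15, learning_rate=0.05, n_buckets=2000, seed=seed)
            a_ctx, _ = cv_alpha(labeled, folds=3, alpha_grid=grid, seed=seed, model="context", hp=hp)
            a_base, _ = cv_alpha(labeled, folds=3, alpha_grid=grid, seed=seed, model="baseline", hp=hp)
            wins += a_ctx >= a_base
        assert wins >= 4


class TestBootstrap:
    def test_identical_scorers_no_difference(self, rng):
        items = [(float(rng.random()), bool(rng.random() < 0.3)) for _ in range(60)]
        items[:2] = [(0.5, True), (0.5, False)]
        scores, labels = scores_labels(items)
        res = bootstrap_compare(scores, scores, labels, n_boot=200, seed=0)
        assert res.mean_diff == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_sds_nonnegative_and_reproducible(self, rng):
        items = [(float(rng.random()), bool(rng.random() < 0.3)) for _ in range(60)]
        items[:2] = [(0.5, True), (0.5, False)]
        scores, labels = scores_labels(items)
        other = {p: 1.0 - s for p, s in scores.items()}
        r1 = bootstrap_compare(scores, other, labels, n_boot=150, seed=4)
        r2 = bootstrap_compare(scores, other, labels, n_boot=150, seed=4)
        assert r1 == r2
        assert r1.sd_a >= 0 and r1.sd_b >= 0

    def test_clearly_better_scorer_significant(self, rng):
        y = rng.random(200) < 0.3
        y[:2] = [True, False]
        good = {make_pair(k, k): float(y[k]) * 0.8 + float(rng.random()) * 0.2 for k in range(200)}
        noise = {make_pair(k, k): float(rng.random()) for k in range(200)}
        labels = {make_pair(k, k): bool(y[k]) for k in range(200)}
        res = bootstrap_compare(good, noise, labels, n_boot=300, seed=1)
        assert res.mean_diff > 0
        assert res.p_value < 0.001


def test_pair_labels_from_comentions():
    records = [
        Comention("d1", 0, make_pair(1, 1), "t .", label="positive"),
        Comention("d1", 1, make_pair(2, 2), "t .", label="negative"),
        Comention("d1", 2, make_pair(3, 3), "t .", label="excluded_grey"),
        Comention("d1", 3, make_pair(4, 4), "t .", label="excluded_unknown"),
    ]
    labels = pair_labels(records)
    assert labels == {make_pair(1, 1): True, make_pair(2, 2): False}
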