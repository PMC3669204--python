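import itertools
import math

import numpy as np
import pytest

from hrss import (
    BUILTIN_SCHEMES,
    ConfidenceScheme,
    LabeledScore,
    best_f1,
    confidence_bin,
    confusion_at,
    f1_at,
    pearson,
    roc_curve,
    youden_index,
    zscore_orthologs,
)
from hrss.errors import DegenerateInputError

from conftest import mann_whitney_auc, pearson_closed_form

POS = [0.9, 0.7, 0.7, 0.3]
NEG = [0.8, 0.4, 0.2, 0.1]


def labeled(pos, neg):
    return [LabeledScore(f"p{i}", s, 1) for i, s in enumerate(pos)] + [
        LabeledScore(f"n{i}", s, 0) for i, s in enumerate(neg)
    ]


def random_labeled(rng, n=30):
    scores = np.round(rng.random(n), 2)  # rounding forces ties
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return [LabeledScore(str(i), float(s), int(l)) for i, (s, l) in enumerate(zip(scores, labels))]


class TestConfusion:
    def test_eight_score_example(self):
        c = confusion_at(labeled(POS, NEG), 0.5)
        assert (c.tp, c.fn, c.fp, c.tn) == (3, 1, 1, 3)
        assert c.tpr == 0.75 and c.fpr == 0.25
        assert c.ppv == 0.75 and c.npv == 0.75

    def test_threshold_below_everything(self):
        c = confusion_at(labeled(POS, NEG), 0.0)
        assert c.tpr == 1.0 and c.fpr == 1.0

    def test_threshold_above_everything(self):
        c = confusion_at(labeled(POS, NEG), 2.0)
        assert c.tpr == 0.0 and c.fpr == 0.0
        assert c.ppv is None

    def test_single_class_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            confusion_at([LabeledScore("p", 0.5, 1)], 0.3)

    def test_ties_predicted_positive(self):
        c = confusion_at(labeled(POS, NEG), 0.7)
        assert c.tp == 3  # both 0.7 scores included


class TestRocCurve:
    def test_perfect_separation(self):
        assert roc_curve(labeled([0.9, 0.8], [0.2, 0.1])).auc == pytest.approx(1.0)

    def test_eight_score_auc(self):
        assert roc_curve(labeled(POS, NEG)).auc == pytest.approx(mann_whitney_auc(POS, NEG))
        assert roc_curve(labeled(POS, NEG)).auc == pytest.approx(0.75)

    def test_endpoints_present(self):
        curve = roc_curve(labeled(POS, NEG))
        assert (curve.points[0].fpr, curve.points[0].tpr) == (0.0, 0.0)
        assert (curve.points[-1].fpr, curve.points[-1].tpr) == (1.0, 1.0)

    def test_monotone_as_threshold_decreases(self):
        curve = roc_curve(labeled(POS, NEG))
        for p, q in zip(curve.points, curve.points[1:]):
            assert q.fpr >= p.fpr and q.tpr >= p.tpr

    def test_shuffled_labels_auc_near_half(self):
        rng = np.random.default_rng(11)
        scores = rng.random(2000)
        labels = rng.integers(0, 2, size=2000)
        data = [LabeledScore(str(i), float(s), int(l)) for i, (s, l) in enumerate(zip(scores, labels))]
        assert roc_curve(data).auc == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_mann_whitney_on_random_sets(self, seed):
        rng = np.random.default_rng(seed)
        data = random_labeled(rng, n=int(rng.integers(5, 50)))
        pos = [s.score for s in data if s.label == 1]
        neg = [s.score for s in data if s.label == 0]
        assert roc_curve(data).auc == pytest.approx(mann_whitney_auc(pos, neg))

    def test_complement_sums_to_one_without_ties(self):
        rng = np.random.default_rng(5)
        scores = rng.random(40)  # continuous, no ties
        labels = rng.integers(0, 2, size=40)
        labels[0], labels[1] = 0, 1
        data = [LabeledScore(str(i), float(s), int(l)) for i, (s, l) in enumerate(zip(scores, labels))]
        neg_data = [LabeledScore(s.pair, -s.score, s.label) for s in data]
        assert roc_curve(data).auc + roc_curve(neg_data).auc == pytest.approx(1.0)


class TestYouden:
    def test_eight_score_example(self):
        t, y = youden_index(roc_curve(labeled(POS, NEG)))
        assert y == pytest.approx(0.5)
        # Y=0.5 is attained at thresholds 0.7 and 0.3; ties take the smallest
        assert t == pytest.approx(0.3)

    def test_perfect_classifier(self):
        _t, y = youden_index(roc_curve(labeled([0.9, 0.8], [0.2, 0.1])))
        assert y == pytest.approx(1.0)

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(3)
        scores = rng.random(3000)
        labels = rng.integers(0, 2, size=3000)
        data = [LabeledScore(str(i), float(s), int(l)) for i, (s, l) in enumerate(zip(scores, labels))]
        _t, y = youden_index(roc_curve(data))
        assert y < 0.1

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(100 + seed)
        data = random_labeled(rng)
        curve = roc_curve(data)
        t, y = youden_index(curve)
        best = max(
            confusion_at(data, th).tpr - confusion_at(data, th).fpr for th in curve.thresholds
        )
        assert y == pytest.approx(best)
        assert confusion_at(data, t).tpr - confusion_at(data, t).fpr == pytest.approx(y)


class TestF1:
    def test_eight_score_example(self):
        assert f1_at(labeled(POS, NEG), 0.5) == pytest.approx(0.75)

    def test_perfect_classifier(self):
        assert f1_at(labeled([0.9, 0.8], [0.2, 0.1]), 0.5) == pytest.approx(1.0)

    def test_undefined_above_all_scores(self):
        assert f1_at(labeled(POS, NEG), 5.0) is None

    def test_best_f1_brute_force(self):
        rng = np.random.default_rng(9)
        data = random_labeled(rng)
        t, f = best_f1(data)
        curve = roc_curve(data)
        candidates = [(th, f1_at(data, th)) for th in curve.thresholds]
        best = max(v for _th, v in candidates if v is not None)
        assert f == pytest.approx(best)


class TestConfidenceBins:
    def test_table_intervals(self):
        expected = {
            "yeast-bp": ("[0, 0.1)", "[0.1, 0.2)", "[0.2, 0.7)", "[0.7, 1]"),
            "yeast-cc": ("[0, 0.1)", "[0.1, 0.2)", "[0.2, 0.5)", "[0.5, 1]"),
            "human-bp": ("[0, 0.1)", "[0.1, 0.2)", "[0.2, 0.6)", "[0.6, 1]"),
            "human-cc": ("[0, 0.1)", "[0.1, 0.2)", "[0.2, 0.5)", "[0.5, 1]"),
        }
        for name, intervals in expected.items():
            assert BUILTIN_SCHEMES[name].intervals() == intervals

    def test_examples(self):
        assert confidence_bin(0.75, BUILTIN_SCHEMES["yeast-bp"]) == "H"
        assert confidence_bin(0.5, BUILTIN_SCHEMES["human-cc"]) == "H"
        assert confidence_bin(0.0, BUILTIN_SCHEMES["yeast-bp"]) == "L"

    def test_boundaries(self):
        s = BUILTIN_SCHEMES["yeast-bp"]
        assert confidence_bin(0.1, s) == "M_L"
        assert confidence_bin(0.2, s) == "M_H"
        assert confidence_bin(0.7, s) == "H"
        assert confidence_bin(1.0, s) == "H"

    def test_partition_of_unit_interval(self):
        for scheme in BUILTIN_SCHEMES.values():
            for x in np.linspace(0, 1, 101):
                label = confidence_bin(float(x), scheme)
                assert label in ("L", "M_L", "M_H", "H")

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            confidence_bin(1.5, BUILTIN_SCHEMES["yeast-bp"])
        with pytest.raises(ValueError):
            confidence_bin(-0.1, BUILTIN_SCHEMES["yeast-bp"])

    def test_invalid_cuts(self):
        with pytest.raises(ValueError):
            ConfidenceScheme("bad", (0.2, 0.1, 0.7))


class TestZScore:
    def test_two_pair_enumerable_null(self):
        table = {("a1", "b1"): 1.0, ("a2", "b2"): 1.0, ("a1", "b2"): 0.0, ("a2", "b1"): 0.0}
        rep = zscore_orthologs([("a1", "b1"), ("a2", "b2")], lambda a, b: table[(a, b)], reps=10_000, seed=0)
        assert rep.asv_observed == 1.0
        # exhaustive null over the 2 bijections: {1.0, 0.0}, mean 0.5
        stderr = rep.null_stdev / math.sqrt(rep.reps)
        assert abs(rep.null_mean - 0.5) < 3 * stderr

    def test_bit_reproducible(self):
        rng_table = np.random.default_rng(4)
        pairs = [(f"a{i}", f"b{i}") for i in range(6)]
        vals = {
            (a, b): float(rng_table.random())
            for a in [p[0] for p in pairs]
            for b in [p[1] for p in pairs]
        }
        r1 = zscore_orthologs(pairs, lambda a, b: vals[(a, b)], reps=100, seed=42)
        r2 = zscore_orthologs(pairs, lambda a, b: vals[(a, b)], reps=100, seed=42)
        assert r1 == r2

    def test_constant_scorer_is_degenerate(self):
        pairs = [(f"a{i}", f"b{i}") for i in range(4)]
        with pytest.raises(DegenerateInputError):
            zscore_orthologs(pairs, lambda a, b: 0.7, reps=50, seed=1)

    def test_conserved_pairs_give_large_z(self):
        pairs = [(f"h{i}", f"m{i}") for i in range(20)]
        rep = zscore_orthologs(
            pairs, lambda a, b: 1.0 if a[1:] == b[1:] else 0.0, reps=200, seed=42
        )
        assert rep.z > 10

    def test_none_scores_dropped_and_counted(self):
        pairs = [("a", "x"), ("b", "y"), ("c", "z")]
        vals = {("a", "x"): 0.9, ("b", "y"): None}
        rep = zscore_orthologs(
            pairs, lambda a, b: vals.get((a, b), 0.1), reps=50, seed=0
        )
        assert rep.n_dropped == 1
        assert rep.asv_observed == pytest.approx((0.9 + 0.1) / 2)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateInputError):
            zscore_orthologs([("a", "b")], lambda a, b: 1.0, reps=10, seed=0)

    def test_bad_reps(self):
        with pytest.raises(ValueError):
            zscore_orthologs([("a", "b"), ("c", "d")], lambda a, b: 1.0, reps=0, seed=0)


class TestPearson:
    def test_affine(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_negation(self):
        x = [1.0, 2.0, 3.0]
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_four_point_example(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(
            pearson_closed_form([1, 2, 3, 4], [1, 3, 2, 4])
        )

    def test_zero_variance_undefined(self):
        assert pearson([1, 2, 3], [5, 5, 5]) is None

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pearson([1, 2, 3], [1, 2])
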