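"""Threshold-sweep curves, AUC oracle equivalence, and the two rankers."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import germdeconv as gd
from tests.conftest import labels_from, make_matrix


def series(scores, genes=None):
    genes = genes or [f"g{i}" for i in range(1, len(scores) + 1)]
    return pd.Series(np.asarray(scores, dtype=float), index=genes)


def brute_force_auc(scores, labels):
    """Pairwise concordance: P(random positive > random negative), ties 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


def brute_force_average_precision(scores, labels):
    """AP from exhaustive threshold enumeration at every distinct score."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    y = np.asarray(labels)[order]
    s = np.asarray(scores)[order]
    n_pos = (y == 1).sum()
    ap, prev_recall = 0.0, 0.0
    for t in sorted(set(s), reverse=True):
        k = (s >= t).sum()
        tp = (y[:k] == 1).sum()
        recall, precision = tp / n_pos, tp / k
        if recall > prev_recall:
            ap += (recall - prev_recall) * precision
            prev_recall = recall
    return ap


class TestPRCurve:
    def test_hand_enumerated_example(self):
        scores = series([0.9, 0.8, 0.7, 0.6])
        labels = labels_from(["g1", "g3"], ["g2", "g4"])
        curve = gd.pr_curve(scores, labels, step=0.002)
        full = curve.table[curve.table["recall"] >= 1.0]
        assert full.iloc[0]["precision"] == pytest.approx(2 / 3)

    def test_perfect_ranking_precision_one_everywhere(self):
        scores = series([4, 3, 2, 1])
        labels = labels_from(["g1", "g2"], ["g3", "g4"])
        curve = gd.pr_curve(scores, labels, step=0.5)
        assert (curve.precision == 1.0).sum() >= 1
        head = curve.table[curve.table["recall"] <= 1.0]
        # positives all outrank negatives: precision 1 until recall hits 1
        assert (head[head["recall"] < 1.0]["precision"] == 1.0).all()

    def test_final_precision_equals_prevalence_exactly(self):
        rng = np.random.default_rng(0)
        scores = series(rng.random(200))
        labels = labels_from([f"g{i}" for i in range(1, 61)],
                             [f"g{i}" for i in range(61, 201)])
        curve = gd.pr_curve(scores, labels, step=0.002)
        assert curve.table.iloc[-1]["recall"] == 1.0
        assert curve.table.iloc[-1]["precision"] == 60 / 200

    def test_recall_monotone_along_sweep(self):
        rng = np.random.default_rng(1)
        scores = series(rng.normal(size=150))
        labels = labels_from([f"g{i}" for i in range(1, 51)],
                             [f"g{i}" for i in range(51, 151)])
        curve = gd.pr_curve(scores, labels, step=0.1)
        assert (np.diff(curve.recall) >= 0).all()

    def test_random_scores_precision_near_prevalence(self):
        """Random ranking of a 129/159 split: every precision ~ 45%."""
        rng = np.random.default_rng(7)
        pos = [f"p{i}" for i in range(129)]
        neg = [f"n{i}" for i in range(159)]
        labels = labels_from(pos, neg)
        precisions = []
        for seed in range(5):
            scores = series(np.random.default_rng(seed).random(288), pos + neg)
            curve = gd.pr_curve(scores, labels, step=0.002)
            tail = curve.table[curve.table["recall"] >= 0.5]
            precisions.append(tail["precision"].mean())
        assert np.mean(precisions) == pytest.approx(129 / 288, abs=0.04)

    def test_errors(self):
        scores = series([1.0, 2.0])
        with pytest.raises(ValueError, match="step"):
            gd.pr_curve(scores, labels_from(["g1"], ["g2"]), step=0.0)
        with pytest.raises(ValueError, match="non-finite"):
            gd.pr_curve(series([np.nan, 1.0]), labels_from(["g1"], ["g2"]),
                        step=0.1)


class TestPrecisionAtRecall:
    def test_perfect_ranking(self):
        scores = series([4, 3, 2, 1])
        labels = labels_from(["g1", "g2"], ["g3", "g4"])
        curve = gd.pr_curve(scores, labels, step=0.5)
        assert gd.precision_at_recall(curve, 0.10) == 1.0

    def test_hand_example_full_recall(self):
        scores = series([0.9, 0.8, 0.7, 0.6])
        labels = labels_from(["g1", "g3"], ["g2", "g4"])
        curve = gd.pr_curve(scores, labels, step=0.002)
        assert gd.precision_at_recall(curve, 1.0) == pytest.approx(2 / 3)

    def test_random_oocyte_split_near_prevalence(self):
        """Random 46/138 ranking: precision at 10% recall ~ 25%."""
        labels = labels_from([f"p{i}" for i in range(46)],
                             [f"n{i}" for i in range(138)])
        vals = []
        for seed in range(10):
            scores = series(np.random.default_rng(100 + seed).random(184),
                            list(labels.labels.index))
            curve = gd.pr_curve(scores, labels, step=0.002)
            vals.append(gd.precision_at_recall(curve, 0.10))
        assert np.mean(vals) == pytest.approx(46 / 184, abs=0.08)

    def test_unreachable_recall_rejected(self):
        scores = series([4, 3])
        labels = labels_from(["g1"], ["g2"])
        curve = gd.pr_curve(scores, labels, step=0.5)
        with pytest.raises(ValueError, match="exceeds"):
            gd.precision_at_recall(curve, 1.5)


class TestAveragePrecision:
    def test_perfect_ranking_is_one(self):
        scores = series([4, 3, 2, 1])
        labels = labels_from(["g1", "g2"], ["g3", "g4"])
        assert gd.average_precision(
            gd.pr_curve(scores, labels, step=0.5)
        ) == pytest.approx(1.0)

    def test_worst_case_matches_brute_force(self):
        # all negatives first: k positives of n genes
        k, n = 3, 10
        scores = list(range(n, 0, -1))
        y = [-1] * (n - k) + [1] * k
        genes = [f"g{i}" for i in range(n)]
        labels = gd.TrainingSet(pd.Series(y, index=genes, dtype=int))
        curve = gd.pr_curve(series(scores, genes), labels, step=0.5)
        expected = brute_force_average_precision(scores, y)
        assert gd.average_precision(curve) == pytest.approx(expected)

    def test_random_scores_near_positive_fraction(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(400)]
        labels = labels_from(genes[:100], genes[100:])
        aps = []
        for seed in range(5):
            scores = series(np.random.default_rng(seed).random(400), genes)
            aps.append(gd.average_precision(
                gd.pr_curve(scores, labels, step=0.002)
            ))
        assert np.mean(aps) == pytest.approx(0.25, abs=0.05)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-50, 50).map(lambda v: v / 10.0),
                    min_size=6, max_size=20, unique=True),
           st.data())
    def test_invariant_under_monotone_transform(self, scores, data):
        """AP depends only on the ranking once the sweep resolves all scores."""
        n = len(scores)
        n_pos = data.draw(st.integers(1, n - 1))
        y = [1] * n_pos + [-1] * (n - n_pos)
        genes = [f"g{i}" for i in range(n)]
        labels = gd.TrainingSet(pd.Series(y, index=genes, dtype=int))

        def resolving_step(vals):
            gaps = np.diff(np.sort(np.asarray(vals, dtype=float)))
            gaps = gaps[gaps > 0]
            return max(float(gaps.min()) / 2, 1e-9) if len(gaps) else 1.0

        base = gd.average_precision(gd.pr_curve(
            series(scores, genes), labels, step=resolving_step(scores)
        ))
        transformed = np.exp(np.asarray(scores) / 5.0)  # strictly monotone
        other = gd.average_precision(gd.pr_curve(
            series(transformed, genes), labels, step=resolving_step(transformed)
        ))
        assert base == pytest.approx(other, abs=1e-9)


class TestROC:
    def test_perfect_ranking_auc_one(self):
        scores = series([4, 3, 2, 1])
        labels = labels_from(["g1", "g2"], ["g3", "g4"])
        _, auc = gd.roc_auc(scores, labels)
        assert auc == 1.0

    def test_hand_example(self):
        scores = series([4, 3, 2, 1])
        labels = labels_from(["g1", "g3"], ["g2", "g4"])
        _, auc = gd.roc_auc(scores, labels)
        assert auc == pytest.approx(0.75)

    def test_matches_brute_force_on_random_instances(self):
        """Oracle equivalence on 50 random instances of <= 200 genes."""
        rng = np.random.default_rng(12345)
        for _ in range(50):
            n = int(rng.integers(10, 201))
            n_pos = int(rng.integers(1, n))
            y = np.array([1] * n_pos + [-1] * (n - n_pos))
            rng.shuffle(y)
            # tie-free scores
            scores = rng.permutation(n).astype(float)
            genes = [f"g{i}" for i in range(n)]
            labels = gd.TrainingSet(pd.Series(y, index=genes, dtype=int))
            _, auc = gd.roc_auc(series(scores, genes), labels)
            assert auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_ties_counted_half(self):
        scores = series([1.0, 1.0])
        labels = labels_from(["g1"], ["g2"])
        _, auc = gd.roc_auc(scores, labels)
        assert auc == 0.5

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(1000)]
        y = rng.permutation([1] * 300 + [-1] * 700)
        labels = gd.TrainingSet(pd.Series(y, index=genes, dtype=int))
        _, auc = gd.roc_auc(series(rng.random(1000), genes), labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        scores = series([1.0, 2.0])
        with pytest.raises(ValueError, match="both classes"):
            gd.roc_auc(scores, pd.Series([1, 1], index=["g1", "g2"]))


class TestExpressionLevelBaseline:
    def test_constant_matrix_precision_is_prevalence(self):
        m = make_matrix(np.full((10, 4), 5.0))
        labels = labels_from([f"g{i}" for i in range(1, 4)],
                             [f"g{i}" for i in range(4, 11)])
        _, curve = gd.expression_level_baseline(m, labels)
        assert (curve.precision == 0.3).all()

    def test_score_is_mean_across_timepoints(self):
        m = make_matrix([[1, 2, 3, 4], [10, 10, 10, 10]])
        labels = labels_from(["g2"], ["g1"])
        scores, _ = gd.expression_level_baseline(m, labels)
        assert scores["g1"] == pytest.approx(2.5)
        assert scores["g2"] == pytest.approx(10.0)

    def test_replicates_averaged_before_scoring(self):
        m = make_matrix([[0, 4, 2, 6]], times=[1, 1, 2, 2],
                        replicates=[1, 2, 1, 2])
        labels = gd.TrainingSet(pd.Series([1, -1], index=["g1", "g1b"]))
        m = make_matrix([[0, 4, 2, 6], [1, 1, 1, 1]], genes=["g1", "g1b"],
                        times=[1, 1, 2, 2], replicates=[1, 2, 1, 2])
        scores, _ = gd.expression_level_baseline(m, labels)
        assert scores["g1"] == pytest.approx(3.0)


class TestCorrelationPairBaseline:
    def test_pair_labels_and_counts(self):
        # 2 positives + 2 negatives -> 6 pairs: 2 same-type, 4 cross
        m = make_matrix(np.random.default_rng(0).normal(size=(4, 4)),
                        genes=["p1", "p2", "n1", "n2"])
        labels = labels_from(["p1", "p2"], ["n1", "n2"])
        pairs, _ = gd.correlation_pair_baseline(m, labels)
        assert len(pairs) == 6
        assert (pairs["label"] == 1).sum() == 2
        assert (pairs["label"] == -1).sum() == 4

    def test_identical_and_opposite_profiles(self):
        m = make_matrix([[1, 2, 3, 4], [1, 2, 3, 4], [4, 3, 2, 1], [0, 5, 1, 6]],
                        genes=["a", "b", "c", "d"])
        labels = labels_from(["a", "b"], ["c", "d"])
        pairs, _ = gd.correlation_pair_baseline(m, labels)
        lookup = {(r.gene_a, r.gene_b): r.correlation
                  for r in pairs.itertuples()}
        assert lookup[("a", "b")] == pytest.approx(1.0)
        assert lookup[("a", "c")] == pytest.approx(-1.0)

    def test_zero_variance_profile_pairs_dropped(self, caplog):
        m = make_matrix([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1],
                         [2, 4, 1, 3]], genes=["a", "b", "c", "d"])
        labels = labels_from(["a", "b"], ["c", "d"])
        with caplog.at_level("WARNING"):
            pairs, _ = gd.correlation_pair_baseline(m, labels)
        assert len(pairs) == 3  # pairs among {a, c, d} only
        assert "b" not in set(pairs["gene_a"]) | set(pairs["gene_b"])

    def test_too_few_timepoints_rejected(self):
        m = make_matrix([[1, 2], [3, 4], [5, 6], [7, 8]],
                        genes=["a", "b", "c", "d"])
        labels = labels_from(["a", "b"], ["c", "d"])
        with pytest.raises(ValueError, match="3 time points"):
            gd.correlation_pair_baseline(m, labels)


def test_pair_prevalence_combinatorics():
    labels = labels_from(["p1", "p2"], ["n1", "n2"])
    assert gd.pair_prevalence(labels) == pytest.approx(2 / 6)
    labels = labels_from([f"p{i}" for i in range(129)],
                         [f"n{i}" for i in range(159)])
    import math
    expected = (math.comb(129, 2) + math.comb(159, 2)) / math.comb(288, 2)
    assert gd.pair_prevalence(labels) == pytest.approx(expected)
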