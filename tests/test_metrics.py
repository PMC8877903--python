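"""The metric formulary against brute-force label-vector oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from rpecg.metrics import (
    ConfusionMatrix,
    cohen_kappa,
    confusion_matrix,
    metrics_report,
    per_class_counts,
    ppv_bayes,
    roc_auc_threshold,
)


def labels_from_matrix(cm):
    """Regenerate (y_true, y_pred) vectors realizing a confusion matrix."""
    y_true, y_pred = [], []
    for i, p in enumerate(cm.labels):
        for j, a in enumerate(cm.labels):
            y_true += [a] * cm.counts[i, j]
            y_pred += [p] * cm.counts[i, j]
    return y_true, y_pred


def random_matrices(n=100, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        k = int(rng.integers(2, 7))
        labels = tuple(f"c{i}" for i in range(k))
        counts = rng.integers(0, 30, size=(k, k))
        if counts.sum() == 0:
            counts[0, 0] = 1
        yield ConfusionMatrix(counts, labels)


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        cm = confusion_matrix(list("AABBC"), list("AABBC"), labels="ABC")
        assert np.array_equal(np.diag(np.diag(cm.counts)), cm.counts)

    def test_small_tally(self):
        cm = confusion_matrix(["A", "A", "B", "C"], ["A", "B", "B", "C"],
                              labels="ABC")
        assert cm.counts[cm.index("B"), cm.index("A")] == 1
        assert list(np.diag(cm.counts)) == [1, 1, 1]

    def test_column_sums_are_actual_counts(self):
        y_true = list("AAABBBBCC")
        y_pred = list("ABCBBACCA")
        cm = confusion_matrix(y_true, y_pred, labels="ABC")
        for j, lab in enumerate(cm.labels):
            assert cm.counts[:, j].sum() == y_true.count(lab)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["A", "D"], ["A", "A"], labels="ABC")

    def test_roundtrip_through_label_vectors(self):
        for cm in random_matrices(20, seed=3):
            y_true, y_pred = labels_from_matrix(cm)
            back = confusion_matrix(y_true, y_pred, cm.labels)
            assert np.array_equal(back.counts, cm.counts)


class TestPerClassCounts:
    def test_three_class_complement_form(self):
        # TN(A) must exclude everything in A's predicted row and actual column
        cm = ConfusionMatrix(np.arange(1, 10).reshape(3, 3), "ABC")
        tp, fp, fn, tn = per_class_counts(cm, "A")
        c = cm.counts
        assert tp == c[0, 0]
        assert fp == c[0, 1] + c[0, 2]
        assert fn == c[1, 0] + c[2, 0]
        assert tn == c[1, 1] + c[2, 1] + c[1, 2] + c[2, 2]

    def test_counts_partition_total(self):
        for cm in random_matrices(30, seed=1):
            for lab in cm.labels:
                assert sum(per_class_counts(cm, lab)) == cm.total

    def test_perfect_matrix_has_no_errors(self):
        cm = ConfusionMatrix(np.diag([3, 4, 5]), "ABC")
        for lab in cm.labels:
            tp, fp, fn, tn = per_class_counts(cm, lab)
            assert fp == 0 and fn == 0

    def test_against_label_vector_oracle(self):
        for cm in random_matrices(50, seed=2):
            y_true, y_pred = labels_from_matrix(cm)
            for lab in cm.labels:
                tp = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p == lab)
                fp = sum(1 for t, p in zip(y_true, y_pred) if t != lab and p == lab)
                fn = sum(1 for t, p in zip(y_true, y_pred) if t == lab and p != lab)
                tn = len(y_true) - tp - fp - fn
                assert per_class_counts(cm, lab) == (tp, fp, fn, tn)


class TestMetricsReport:
    def test_perfect_matrix(self):
        rep = metrics_report(ConfusionMatrix(np.diag([5, 6, 7]), "ABC"))
        assert rep.acc_micro == 1.0
        assert rep.kappa == 1.0
        for d in rep.per_class.values():
            assert d["sens"] == 1.0 and d["sp"] == 1.0

    def test_bayes_ppv_worked_example(self):
        # Sens 0.9, Sp 0.8, P 0.1 -> 0.09 / (0.09 + 0.2 * 0.9) = 1/3
        assert np.isclose(ppv_bayes(0.9, 0.8, 0.1), 1 / 3)

    def test_oracle_equivalence_on_random_matrices(self):
        for cm in random_matrices(100, seed=7):
            y_true, y_pred = labels_from_matrix(cm)
            n = len(y_true)
            rep = metrics_report(cm)
            po = sum(t == p for t, p in zip(y_true, y_pred)) / n
            assert abs(rep.acc_micro - po) < 1e-12
            pe = sum(
                (y_pred.count(l) / n) * (y_true.count(l) / n) for l in cm.labels
            )
            if pe < 1:
                assert abs(rep.kappa - (po - pe) / (1 - pe)) < 1e-12
            for lab in cm.labels:
                d = rep.per_class[lab]
                tp, fp, fn, tn = per_class_counts(cm, lab)
                if tp + fn:
                    assert abs(d["sens"] - tp / (tp + fn)) < 1e-12
                else:
                    assert np.isnan(d["sens"])
                if tn + fp:
                    assert abs(d["sp"] - tn / (tn + fp)) < 1e-12
                prev = (tp + fn) / n
                if not np.isnan(d["sens"]) and not np.isnan(d["sp"]):
                    den = d["sens"] * prev + (1 - d["sp"]) * (1 - prev)
                    if den > 0:
                        assert abs(d["ppv"] - d["sens"] * prev / den) < 1e-12

    def test_kappa_matches_sklearn(self):
        for cm in random_matrices(30, seed=11):
            y_true, y_pred = labels_from_matrix(cm)
            if len(set(y_true) | set(y_pred)) < 2:
                continue
            ours = cohen_kappa(cm)
            theirs = cohen_kappa_score(y_true, y_pred, labels=list(cm.labels))
            if not np.isnan(theirs):
                assert abs(ours - theirs) < 1e-12

    def test_kappa_near_zero_for_independent_predictions(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("ABC"), size=10_000, p=[0.5, 0.3, 0.2])
        y_pred = rng.permutation(y_true)
        cm = confusion_matrix(list(y_true), list(y_pred), "ABC")
        assert abs(cohen_kappa(cm)) < 0.05

    def test_minority_class_defaults_to_smallest(self):
        counts = np.array([[50, 0, 1], [0, 40, 0], [2, 1, 3]])
        rep = metrics_report(ConfusionMatrix(counts, "ABC"))
        assert rep.minority_class == "C"

    def test_undefined_rates_are_nan(self):
        # class C never occurs: sens undefined
        cm = confusion_matrix(list("AB"), list("AB"), "ABC")
        rep = metrics_report(cm)
        assert np.isnan(rep.per_class["C"]["sens"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics_report(ConfusionMatrix(np.zeros((2, 2), dtype=int), "AB"))

    def test_macro_reporting_shape(self):
        rep = metrics_report(ConfusionMatrix(np.diag([5, 5]), "AB"))
        mean, sd = rep.sens_macro
        assert mean == 1.0 and sd == 0.0


def rank_sum_auc(scores, truths):
    """P(random positive outranks random negative), ties counted 1/2."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert 0.2 < roc.chosen_threshold <= 0.8

    def test_identical_scores_give_half(self):
        roc = roc_auc_threshold([0.5] * 10, [1, 0] * 5)
        assert np.isclose(roc.auc, 0.5)

    def test_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.random(n), 2)  # force some ties
            truths = rng.integers(0, 2, size=n)
            if truths.min() == truths.max():
                continue
            roc = roc_auc_threshold(scores, truths)
            assert np.isclose(roc.auc, rank_sum_auc(scores, truths), atol=1e-12)
            assert np.isclose(roc.auc, roc_auc_score(truths, scores), atol=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.random(50)
        truths = rng.integers(0, 2, size=50)
        a = roc_auc_threshold(scores, truths).auc
        b = roc_auc_threshold(np.exp(3 * scores), truths).auc
        assert np.isclose(a, b, atol=1e-12)

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(7)
        roc = roc_auc_threshold(rng.random(40), rng.integers(0, 2, size=40))
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_threshold([0.1, 0.2], [1, 1])

    def test_youden_threshold_maximizes_j(self):
        scores = [0.9, 0.7, 0.6, 0.4, 0.2]
        truths = [1, 1, 0, 1, 0]
        roc = roc_auc_threshold(scores, truths)
        j = roc.tpr - roc.fpr
        chosen = np.nonzero(roc.thresholds == roc.chosen_threshold)[0][0]
        assert j[chosen] == j.max()


class TestCollapse:
    def test_superclass_collapse_preserves_total(self):
        cm = ConfusionMatrix(np.arange(16).reshape(4, 4),
                             ("AF", "normal", "VF", "noise"))
        merged = cm.collapse({"AF": "other", "normal": "other"},
                             ("other", "VF", "noise"))
        assert merged.total == cm.total
        assert merged.counts[0, 0] == (cm.counts[:2, :2]).sum()
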