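"""Metrics: confusion counts, macro averages, Mann-Whitney AUC, DeLong CI."""

import numpy as np
import pytest
from sklearn.metrics import precision_score, recall_score, roc_auc_score

from oralscope.evaluate import (
    AucResult,
    ConfusionMatrix,
    confusion_matrix,
    delong_ci,
    macro_metrics,
    ovr_auc,
    per_class_rates,
)


class TestConfusionMatrix:
    def test_all_correct_is_diagonal(self):
        y = np.repeat(np.arange(5), 3)
        cm = confusion_matrix(y, y)
        np.testing.assert_array_equal(cm.counts, np.diag([3] * 5))

    def test_empty_input(self):
        cm = confusion_matrix([], [])
        assert cm.total == 0

    def test_matches_pairwise_tally_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 5, 500)
        p = rng.integers(0, 5, 500)
        cm = confusion_matrix(t, p)
        brute = np.zeros((5, 5), dtype=int)
        for ti, pi in zip(t, p):
            brute[ti, pi] += 1
        np.testing.assert_array_equal(cm.counts, brute)

    def test_length_mismatch_and_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion_matrix([0, 1], [0])
        with pytest.raises(ValueError, match="labels"):
            confusion_matrix([0, 7], [0, 1])


def brute_force_rates(counts, i):
    """TP/FP/FN/TN by explicit enumeration over all cells."""
    C = counts.shape[0]
    tp = counts[i, i]
    fp = sum(counts[t, i] for t in range(C) if t != i)
    fn = sum(counts[i, p] for p in range(C) if p != i)
    tn = sum(counts[t, p] for t in range(C) for p in range(C) if t != i and p != i)
    return tp, fp, fn, tn


class TestPerClassRates:
    def test_diagonal_gives_perfect_rates(self):
        cm = ConfusionMatrix(np.diag([4, 3, 2, 5, 1]))
        for i in range(5):
            assert per_class_rates(cm, i) == (1.0, 1.0, 1.0)

    def test_absent_class_reported_as_zero_with_flag(self):
        counts = np.zeros((5, 5), dtype=int)
        counts[0, 0] = 10  # class 4 never occurs
        cm = ConfusionMatrix(counts)
        se, sp, pr = per_class_rates(cm, 4)
        assert (se, pr) == (0.0, 0.0)
        assert 4 in macro_metrics(cm).undefined_flags

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            counts = rng.integers(0, 30, (5, 5))
            cm = ConfusionMatrix(counts)
            for i in range(5):
                tp, fp, fn, tn = brute_force_rates(counts, i)
                se, sp, pr = per_class_rates(cm, i)
                assert se == (tp / (tp + fn) if tp + fn else 0.0)
                assert sp == (tn / (tn + fp) if tn + fp else 0.0)
                assert pr == (tp / (tp + fp) if tp + fp else 0.0)


class TestMacroMetrics:
    def test_perfect_classifier(self):
        mm = macro_metrics(ConfusionMatrix(np.diag([5] * 5)))
        assert (mm.se_macro, mm.sp_macro, mm.pr_macro, mm.f1) == (1, 1, 1, 1)

    def test_one_class_fully_misclassified(self):
        counts = np.diag([5, 5, 5, 5, 0])
        counts[4, 0] = 5  # every cancer case called normal
        mm = macro_metrics(ConfusionMatrix(counts))
        assert mm.se_macro == pytest.approx(4 / 5)

    def test_matches_formula_recomputation_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            counts = rng.integers(0, 40, (5, 5))
            mm = macro_metrics(ConfusionMatrix(counts))
            ses, sps, prs = [], [], []
            for i in range(5):
                tp, fp, fn, tn = brute_force_rates(counts, i)
                ses.append(tp / (tp + fn) if tp + fn else 0.0)
                sps.append(tn / (tn + fp) if tn + fp else 0.0)
                prs.append(tp / (tp + fp) if tp + fp else 0.0)
            assert mm.se_macro == pytest.approx(np.mean(ses), abs=1e-12)
            assert mm.sp_macro == pytest.approx(np.mean(sps), abs=1e-12)
            assert mm.pr_macro == pytest.approx(np.mean(prs), abs=1e-12)
            if mm.se_macro + mm.pr_macro > 0:
                expected_f1 = (2 * mm.se_macro * mm.pr_macro
                               / (mm.se_macro + mm.pr_macro))
                assert mm.f1 == pytest.approx(expected_f1, abs=1e-12)

    def test_sensitivity_and_precision_agree_with_sklearn(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 5, 400)
        p = rng.integers(0, 5, 400)
        mm = macro_metrics(confusion_matrix(t, p))
        assert mm.se_macro == pytest.approx(
            recall_score(t, p, average="macro", zero_division=0)
        )
        assert mm.pr_macro == pytest.approx(
            precision_score(t, p, average="macro", zero_division=0)
        )

    def test_macro_values_invariant_under_class_permutation(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 25, (5, 5))
        perm = rng.permutation(5)
        mm = macro_metrics(ConfusionMatrix(counts))
        mm_p = macro_metrics(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        assert mm.se_macro == pytest.approx(mm_p.se_macro)
        assert mm.f1 == pytest.approx(mm_p.f1)


class TestOvrAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert ovr_auc(scores, labels, 1) == 1.0

    def test_uninformative_scores_give_half(self):
        scores = np.full(10, 0.5)
        labels = np.array([1] * 4 + [0] * 6)
        assert ovr_auc(scores, labels, 1) == 0.5

    def test_matches_pairwise_count_oracle(self):
        rng = np.random.default_rng(5)
        x = np.round(rng.uniform(0, 1, 50), 2)  # rounding forces ties
        y = rng.integers(0, 2, 50)
        if y.sum() in (0, 50):
            y[0] = 1 - y[0]
        wins = 0.0
        for xi in x[y == 1]:
            for xj in x[y == 0]:
                wins += 1.0 if xi > xj else (0.5 if xi == xj else 0.0)
        expected = wins / (y.sum() * (50 - y.sum()))
        assert ovr_auc(x, y, 1) == pytest.approx(expected, abs=1e-12)
        assert ovr_auc(x, y, 1) == pytest.approx(roc_auc_score(y, x))

    def test_multiclass_column_selection(self):
        rng = np.random.default_rng(6)
        probs = rng.dirichlet(np.ones(5), 80)
        labels = rng.integers(0, 5, 80)
        for c in range(5):
            if 0 < (labels == c).sum() < 80:
                assert ovr_auc(probs, labels, c) == pytest.approx(
                    roc_auc_score(labels == c, probs[:, c])
                )

    def test_degenerate_class_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            ovr_auc(np.array([0.1, 0.2]), np.array([1, 1]), 1)


class TestDelongCi:
    def test_matches_reference_implementation(self):
        # frozen cross-check computed once with R pROC's ci.auc(method=
        # 'delong') on this exact seeded fixture
        rng = np.random.default_rng(20260920)
        pos = rng.normal(1.0, 1.0, 60)
        neg = rng.normal(0.0, 1.0, 140)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(60, int), np.zeros(140, int)])
        res = delong_ci(scores, labels, 1)
        assert res.auc == pytest.approx(0.695595238095, abs=1e-9)
        assert res.ci_low == pytest.approx(0.613886790512, abs=1e-9)
        assert res.ci_high == pytest.approx(0.777303685679, abs=1e-9)

    def test_perfect_separation_degenerates_with_warning(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="perfect separation"):
            res = delong_ci(scores, labels, 1)
        assert (res.auc, res.ci_low, res.ci_high) == (1.0, 1.0, 1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(0, 1, 100)
        labels = rng.integers(0, 2, 100)
        labels[0], labels[1] = 0, 1
        a = delong_ci(scores, labels, 1)
        b = delong_ci(scores, 1 - labels, 1)
        assert a.auc == pytest.approx(1 - b.auc, abs=1e-12)
        assert a.ci_low == pytest.approx(1 - b.ci_high, abs=1e-12)
        assert a.ci_high == pytest.approx(1 - b.ci_low, abs=1e-12)

    def test_ci_brackets_auc_and_is_clipped(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(0, 1, 60) + rng.integers(0, 2, 60) * 3.5
        labels = (scores > 1.5).astype(int)
        labels[:3] = 1 - labels[:3]
        res = delong_ci(scores, labels, 1)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
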