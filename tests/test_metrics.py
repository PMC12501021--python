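"""Confusion-matrix metrics, ROC-AUC, and McNemar, checked against
brute-force oracles and independent library implementations."""

import numpy as np
import pytest

from dermofusion.metrics import (PairedPredictions, class_metrics,
                                 confusion_matrix, macro_overall,
                                 mcnemar_test, micro_accuracy, roc_auc,
                                 roc_auc_ovr, tpr_fpr_ratio,
                                 two_proportion_z_test)

# Reported per-class results for a pre-trained DenseNet169 on an ISIC-2018
# test split (AUC, precision, sensitivity columns, seven classes).
TABLE3_AUC = [61.5, 68.9, 94.2, 71.5, 83.5, 91.8, 60.8]
TABLE3_PRECISION = [60.0, 67.0, 93.8, 70.6, 81.1, 93.7, 58.8]
TABLE3_SENSITIVITY = [32.5, 71.5, 95.8, 52.6, 77.4, 97.7, 36.5]
# Hybrid-model per-class sensitivities from the same evaluation
TABLE5_SENSITIVITY = [88.2, 92.5, 92.4, 86.9, 93.8, 99.5, 82.3]


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 1, 1, 2, 2, 2])
        cm = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(cm, np.diag([1, 2, 3]))

    def test_cell_sum_is_sample_count(self, rng):
        y_true = rng.integers(0, 4, 50)
        y_pred = rng.integers(0, 4, 50)
        assert confusion_matrix(y_true, y_pred, 4).sum() == 50

    def test_matches_brute_force_pair_counting(self, rng):
        y_true = rng.integers(0, 3, 40)
        y_pred = rng.integers(0, 3, 40)
        cm = confusion_matrix(y_true, y_pred, 3)
        for t in range(3):
            for p in range(3):
                assert cm[t, p] == int(((y_true == t) & (y_pred == p)).sum())

    def test_out_of_range_label_errors(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 3], [0, 1], 3)


class TestClassMetrics:
    @pytest.mark.parametrize("correct,total,expected", [
        (1337, 1341, 99.7),   # nevi, hybrid model
        (209, 223, 93.7),     # melanoma, hybrid model
        (57, 65, 87.7),       # actinic keratoses, hybrid model
        (1301, 1341, 97.0),   # nevi, DenseNet169 baseline
    ])
    def test_reported_recall_from_confusion_counts(self, correct, total,
                                                   expected):
        cm = np.array([[correct, total - correct], [0, 10]])
        df = class_metrics(cm)
        assert round(df.loc[0, "class_accuracy"], 1) == expected
        assert round(df.loc[0, "sensitivity"], 1) == expected

    def test_perfect_matrix_all_rates_100(self):
        df = class_metrics(np.diag([4, 5, 6]))
        for col in ("precision", "sensitivity", "specificity",
                    "ovr_accuracy", "class_accuracy"):
            np.testing.assert_allclose(df[col], 100.0)

    def test_one_vs_rest_identities(self, rng):
        y_true = rng.integers(0, 5, 80)
        y_pred = rng.integers(0, 5, 80)
        cm = confusion_matrix(y_true, y_pred, 5)
        df = class_metrics(cm)
        assert df["tp"].sum() == np.trace(cm)
        np.testing.assert_array_equal(df[["tp", "fp", "fn", "tn"]].sum(axis=1),
                                      80)

    def test_rates_invariant_to_sample_duplication(self, rng):
        y_true = rng.integers(0, 3, 30)
        y_pred = rng.integers(0, 3, 30)
        df1 = class_metrics(confusion_matrix(y_true, y_pred, 3))
        df2 = class_metrics(confusion_matrix(np.tile(y_true, 2),
                                             np.tile(y_pred, 2), 3))
        for col in ("precision", "sensitivity", "specificity"):
            np.testing.assert_allclose(df1[col], df2[col])

    def test_zero_denominator_gives_nan_not_exception(self):
        cm = np.array([[3, 0], [0, 0]])  # second class absent
        df = class_metrics(cm)
        assert np.isnan(df.loc[1, "sensitivity"])


class TestMacro:
    def test_reported_overall_rows(self):
        assert macro_overall(TABLE3_SENSITIVITY) == 66.29
        assert macro_overall(TABLE3_PRECISION) == 75.00
        assert macro_overall(TABLE3_AUC) == 76.03
        assert macro_overall(TABLE5_SENSITIVITY) == 90.80

    def test_identical_values_pass_through(self):
        assert macro_overall([42.0] * 7) == 42.0

    def test_micro_accuracy_is_trace_over_n(self):
        cm = np.array([[8, 2], [1, 9]])
        assert micro_accuracy(cm) == pytest.approx(85.0)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([0, 1, 0, 1], [0.5] * 4) == 0.5

    def test_four_sample_hand_oracle(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.1, 0.2])

    def test_equals_brute_force_pair_comparison(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.choice(np.linspace(0, 1, 17), n)  # force ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = (pos[:, None] > neg[None]).sum()
            ties = (pos[:, None] == neg[None]).sum()
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc_auc(labels, scores) == pytest.approx(expected)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        labels = rng.integers(0, 2, 100)
        scores = rng.random(100)
        assert roc_auc(labels, scores) == pytest.approx(
            roc_auc_score(labels, scores))

    def test_one_vs_rest_wrapper(self, rng):
        y = rng.integers(0, 3, 60)
        scores = rng.random((60, 3))
        aucs = roc_auc_ovr(y, scores)
        assert aucs.shape == (3,)
        for c in range(3):
            assert aucs[c] == pytest.approx(roc_auc(y == c, scores[:, c]))

    def test_literal_tpr_fpr_ratio(self):
        assert tpr_fpr_ratio(tp=9, fn=1, fp=2, tn=8) == pytest.approx(4.5)
        assert tpr_fpr_ratio(tp=9, fn=1, fp=0, tn=10) == np.inf


class TestMcNemar:
    def test_symmetric_discordance(self):
        statistic, p = mcnemar_test((5, 5), method="chi2")
        assert statistic == 0.0 and p == 1.0

    def test_chi2_closed_form(self):
        statistic, p = mcnemar_test((15, 5), method="chi2")
        assert statistic == pytest.approx(81 / 20)
        from scipy.stats import chi2

        assert p == pytest.approx(chi2.sf(4.05, 1))

    def test_exact_single_discordant_pair(self):
        _, p = mcnemar_test((1, 0), method="exact")
        assert p == 1.0

    def test_auto_switches_on_discordant_total(self):
        assert mcnemar_test((1, 0)) == mcnemar_test((1, 0), method="exact")
        assert mcnemar_test((20, 10)) == mcnemar_test((20, 10), method="chi2")

    def test_no_discordance_errors(self):
        with pytest.raises(ValueError):
            mcnemar_test((0, 0))

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[30, 15], [5, 50]]
        ours_stat, ours_p = mcnemar_test((15, 5), method="chi2")
        ref = sm_mcnemar(table, exact=False, correction=True)
        assert ours_stat == pytest.approx(ref.statistic)
        assert ours_p == pytest.approx(ref.pvalue)
        _, p_exact = mcnemar_test((15, 5), method="exact")
        ref_exact = sm_mcnemar(table, exact=True)
        assert p_exact == pytest.approx(ref_exact.pvalue)

    def test_paired_predictions_from_correctness(self):
        a = [True, True, False, False, True]
        b = [True, False, True, False, False]
        paired = PairedPredictions.from_correctness(a, b)
        assert (paired.b, paired.c) == (2, 1)


def test_two_proportion_z_test_symmetry():
    z1, p1 = two_proportion_z_test(90, 100, 80, 100)
    z2, p2 = two_proportion_z_test(80, 100, 90, 100)
    assert z1 == pytest.approx(-z2)
    assert p1 == pytest.approx(p2)
    assert 0 < p1 < 0.1
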