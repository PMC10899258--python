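"""Metric formulas: confusion counts, per-stage scores, kappa, weighted overalls.

Worked examples use published per-stage values whose derived quantities are
fully determined by the formulas; independent cross-checks go through
sklearn.metrics, which is never the implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score, precision_score, recall_score

from slumbernet.metrics import (
    ConfusionMatrix,
    categorical_cross_entropy,
    cohens_kappa,
    confusion_matrix,
    explained_variance,
    f1_score,
    fold_summary,
    overall_weighted_metrics,
    per_class_kappa,
    per_class_metrics,
    stage_metrics_row,
)


class TestConfusionMatrix:
    def test_perfect_agreement_is_diagonal(self):
        cm = confusion_matrix(["W", "N", "R"], ["W", "N", "R"])
        np.testing.assert_array_equal(cm.counts, np.eye(3, dtype=int))

    def test_single_off_diagonal_cell(self):
        cm = confusion_matrix(["W"] * 7, ["N"] * 7)
        expected = np.zeros((3, 3), dtype=int)
        expected[0, 1] = 7
        np.testing.assert_array_equal(cm.counts, expected)

    def test_matches_brute_force_on_random_vectors(self, rng):
        t = rng.integers(0, 3, 200)
        p = rng.integers(0, 3, 200)
        cm = confusion_matrix(t, p)
        brute = np.array([[np.sum((t == i) & (p == j)) for j in range(3)]
                          for i in range(3)])
        np.testing.assert_array_equal(cm.counts, brute)
        assert cm.total == 200

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix(["W"], ["W", "N"])


class TestPerClassMetrics:
    def test_f1_harmonic_mean_worked_examples(self):
        # fold-1 Wake: P 98.76, R 97.11 -> F1 97.93; mouse-1 Wake: 99.04/98.23 -> 98.63
        assert f1_score(98.76, 97.11) == pytest.approx(97.93, abs=0.005)
        assert f1_score(99.04, 98.23) == pytest.approx(98.63, abs=0.005)

    def test_f1_fixed_point(self):
        assert f1_score(87.3, 87.3) == pytest.approx(87.3)

    def test_zero_true_positives_guarded(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[0, 1] = 5  # every W predicted N
        with pytest.warns(UserWarning):
            m = per_class_metrics(ConfusionMatrix(counts), "W")
        assert m["precision"] == 0 and m["recall"] == 0 and m["f1"] == 0

    def test_against_sklearn_on_random_data(self, rng):
        t = rng.integers(0, 3, 500)
        p = rng.integers(0, 3, 500)
        cm = confusion_matrix(t, p)
        for i, stage in enumerate("WNR"):
            m = per_class_metrics(cm, stage)
            skp = 100 * precision_score(t == i, p == i, zero_division=0)
            skr = 100 * recall_score(t == i, p == i, zero_division=0)
            assert m["precision"] == pytest.approx(skp, abs=1e-9)
            assert m["recall"] == pytest.approx(skr, abs=1e-9)


class TestKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa(np.diag([30, 20, 10])) == pytest.approx(1.0)

    def test_independent_predictions_near_zero(self, rng):
        n = 10_000
        t = rng.integers(0, 3, n)
        p = rng.integers(0, 3, n)
        assert abs(cohens_kappa(confusion_matrix(t, p).counts)) < 0.05

    def test_2x2_hand_computed(self):
        counts = np.array([[40, 10], [20, 30]])
        p_o = 70 / 100
        p_e = (50 * 60 + 50 * 40) / 100 ** 2
        assert cohens_kappa(counts) == pytest.approx((p_o - p_e) / (1 - p_e))

    def test_degenerate_marginals_defined_as_zero(self):
        assert cohens_kappa(np.array([[5, 0], [0, 0]])) == 0.0

    def test_multiclass_matches_sklearn(self, rng):
        t = rng.integers(0, 3, 300)
        p = np.where(rng.random(300) < 0.7, t, rng.integers(0, 3, 300))
        ours = cohens_kappa(confusion_matrix(t, p).counts)
        assert ours == pytest.approx(cohen_kappa_score(t, p), abs=1e-12)

    def test_per_class_kappa_ovr_matches_sklearn(self, rng):
        t = rng.integers(0, 3, 300)
        p = np.where(rng.random(300) < 0.7, t, rng.integers(0, 3, 300))
        cm = confusion_matrix(t, p)
        for i, stage in enumerate("WNR"):
            sk = cohen_kappa_score(t == i, p == i)
            assert per_class_kappa(cm, stage) == pytest.approx(sk, abs=1e-12)


class TestCrossEntropy:
    def test_perfect_predictions_zero_loss(self):
        y = np.eye(3)[[0, 1, 2]]
        assert categorical_cross_entropy(y, y) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_ln3(self):
        y = np.eye(3)[[0, 1, 2, 0]]
        p = np.full((4, 3), 1 / 3)
        assert categorical_cross_entropy(y, p) == pytest.approx(np.log(3))

    def test_matches_term_by_term_evaluation(self, rng):
        y = np.eye(3)[rng.integers(0, 3, 50)]
        raw = rng.random((50, 3)) + 0.01
        p = raw / raw.sum(1, keepdims=True)
        hand = -np.mean([np.log(p[i, y[i].argmax()]) for i in range(50)])
        assert categorical_cross_entropy(y, p) == pytest.approx(hand)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            categorical_cross_entropy(np.eye(3), np.eye(2))


class TestExplainedVariance:
    def test_exact_prediction_is_one(self, rng):
        y = rng.standard_normal(100)
        assert explained_variance(y, y) == pytest.approx(1.0)

    def test_constant_mean_prediction_is_zero(self, rng):
        y = rng.standard_normal(100)
        assert explained_variance(y, np.full(100, y.mean())) == pytest.approx(0.0)

    def test_fixed_offset_is_one(self, rng):
        y = rng.standard_normal(100)
        assert explained_variance(y, y + 2.5) == pytest.approx(1.0)

    def test_zero_variance_truth_rejected(self):
        with pytest.raises(ValueError):
            explained_variance(np.ones(10), np.arange(10.0))


class TestOverallWeighted:
    def test_published_per_stage_values_reproduce_published_overalls(self):
        # per-stage P/R for a prior mouse-scoring CNN; overall values are the
        # cross-weighted means and their harmonic mean, to 1-decimal rounding
        p = np.array([98.6, 99.6, 62.6])
        r = np.array([99.3, 93.9, 99.5])
        op, orr, of1 = overall_weighted_metrics(p, r)
        assert round(op, 1) == 86.7
        assert round(orr, 1) == 97.3
        assert round(of1, 1) == 91.7

    def test_uniform_inputs_pass_through(self):
        op, orr, of1 = overall_weighted_metrics(np.full(3, 88.0), np.full(3, 88.0))
        assert op == orr == of1 == pytest.approx(88.0)

    @given(st.lists(st.floats(1, 100), min_size=3, max_size=3),
           st.lists(st.floats(1, 100), min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_overall_precision_is_convex_combination(self, p, r):
        p, r = np.array(p), np.array(r)
        op, orr, _ = overall_weighted_metrics(p, r)
        assert p.min() - 1e-9 <= op <= p.max() + 1e-9
        assert r.min() - 1e-9 <= orr <= r.max() + 1e-9

    @given(st.lists(st.floats(1, 100), min_size=3, max_size=3),
           st.lists(st.floats(1, 100), min_size=3, max_size=3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_swap_symmetry_leaves_f1_unchanged(self, p, r):
        p, r = np.array(p), np.array(r)
        op, orr, of1 = overall_weighted_metrics(p, r)
        op2, orr2, of12 = overall_weighted_metrics(r, p)
        assert op2 == pytest.approx(orr)
        assert orr2 == pytest.approx(op)
        assert of12 == pytest.approx(of1)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            overall_weighted_metrics(np.zeros(3), np.zeros(3))


class TestFoldSummary:
    def test_mean_of_published_wake_recalls(self):
        folds = pd.DataFrame({"W_recall": [97.11, 96.66, 97.37, 96.72, 97.46]})
        out = fold_summary(folds)
        assert round(out.loc["mean", "W_recall"], 2) == 97.06

    def test_identical_rows_have_zero_sem(self):
        out = fold_summary(pd.DataFrame({"x": [5.0] * 4}))
        assert out.loc["sem", "x"] == 0.0

    def test_two_row_sem_closed_form(self):
        out = fold_summary(pd.DataFrame({"x": [2.0, 6.0]}))
        assert out.loc["sem", "x"] == pytest.approx(abs(2.0 - 6.0) / 2)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fold_summary(pd.DataFrame({"x": [1.0]}))


class TestRandomizedAgreementWithBruteForce:
    def test_all_metrics_agree_with_brute_force_over_many_matrices(self, rng):
        import warnings

        for _ in range(200):
            counts = rng.integers(0, 50, size=(3, 3))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(counts)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row = stage_metrics_row(cm)
            for i, s in enumerate("WNR"):
                tp = counts[i, i]
                fp = counts[:, i].sum() - tp
                fn = counts[i, :].sum() - tp
                tn = counts.sum() - tp - fp - fn
                prec = tp / (tp + fp) if tp + fp else 0.0
                rec = tp / (tp + fn) if tp + fn else 0.0
                acc = (tp + tn) / counts.sum()
                assert row[f"{s}_precision"] == pytest.approx(100 * prec)
                assert row[f"{s}_recall"] == pytest.approx(100 * rec)
                assert row[f"{s}_accuracy"] == pytest.approx(100 * acc)


class TestKappaIdentityProperty:
    @given(st.integers(1, 40), st.integers(1, 40), st.integers(1, 40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_kappa_one_iff_no_off_diagonal_mass(self, a, b, c):
        assert cohens_kappa(np.diag([a, b, c])) == pytest.approx(1.0)
        off = np.diag([a, b, c])
        off[0, 1] += 1
        assert cohens_kappa(off) < 1.0
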