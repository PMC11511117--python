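"""Evaluation metrics: confusion counts, multiclass MCC, split stats, t-test."""

import math

import numpy as np
import pytest
from scipy import stats

import toxcascade as tc


def _cov_form_mcc(actual_idx, predicted_idx, k):
    """Independent covariance-form MCC oracle from one-hot indicators."""
    n = len(actual_idx)
    X = np.zeros((n, k))
    Y = np.zeros((n, k))
    X[np.arange(n), predicted_idx] = 1
    Y[np.arange(n), actual_idx] = 1
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = (Xc * Yc).sum()
    cov_xx = (Xc * Xc).sum()
    cov_yy = (Yc * Yc).sum()
    if cov_xx == 0 or cov_yy == 0:
        return 0.0
    return cov_xy / math.sqrt(cov_xx * cov_yy)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = tc.confusion(["A", "B", "C"], ["A", "B", "C"])
        assert np.array_equal(cm.counts, np.eye(3, dtype=int))

    def test_hand_counted_example(self):
        cm = tc.confusion(["A", "A", "B"], ["A", "B", "B"], labels=["A", "B"])
        assert cm.counts.tolist() == [[1, 1], [0, 1]]

    def test_row_sums_equal_actual_frequencies(self):
        rng = np.random.default_rng(0)
        labels = ["w", "x", "y", "z"]
        for _ in range(10):
            actual = rng.choice(labels, size=60).tolist()
            predicted = rng.choice(labels, size=60).tolist()
            cm = tc.confusion(actual, predicted, labels=labels)
            for i, lab in enumerate(labels):
                assert cm.row_sums()[i] == actual.count(lab)
                assert cm.col_sums()[i] == predicted.count(lab)
            assert cm.total == 60

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tc.confusion(["A"], ["A", "B"])

    def test_unknown_label_raises(self):
        with pytest.raises(ValueError, match="Q"):
            tc.confusion(["A"], ["Q"], labels=["A", "B"])

    def test_csv_round_trip(self, tmp_path):
        cm = tc.confusion(["A", "A", "B"], ["A", "B", "B"], labels=["A", "B"])
        p = tmp_path / "cm.csv"
        cm.to_csv(p)
        back = tc.ConfusionMatrix.from_csv(p)
        assert back.labels == cm.labels
        assert np.array_equal(back.counts, cm.counts)


class TestMulticlassMCC:
    @pytest.mark.parametrize("k", [2, 3, 4, 6])
    def test_identity_matrix_scores_one(self, k):
        cm = tc.ConfusionMatrix(labels=[str(i) for i in range(k)],
                                counts=np.eye(k, dtype=int) * 5)
        assert tc.multiclass_mcc(cm) == pytest.approx(1.0)

    def test_single_column_over_balanced_actuals_scores_zero(self):
        counts = np.zeros((3, 3), dtype=int)
        counts[:, 0] = 10  # everything predicted as the first class
        cm = tc.ConfusionMatrix(labels=["a", "b", "c"], counts=counts)
        assert tc.multiclass_mcc(cm) == 0.0

    def test_fixed_3x3_matrix_matches_covariance_oracle(self):
        counts = np.array([[5, 1, 0], [1, 4, 1], [0, 1, 5]])
        actual, predicted = [], []
        for i in range(3):
            for j in range(3):
                actual += [i] * counts[i, j]
                predicted += [j] * counts[i, j]
        cm = tc.ConfusionMatrix(labels=["a", "b", "c"], counts=counts)
        assert tc.multiclass_mcc(cm) == pytest.approx(
            _cov_form_mcc(np.array(actual), np.array(predicted), 3)
        )

    def test_agrees_with_both_oracles_on_random_labelings(self):
        # dual-route check: covariance form coded here plus scikit-learn
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(42)
        for trial in range(50):
            k = int(rng.integers(2, 6))
            n = int(rng.integers(10, 200))
            actual = rng.integers(0, k, size=n)
            predicted = rng.integers(0, k, size=n)
            cm = tc.confusion(
                [str(a) for a in actual],
                [str(p) for p in predicted],
                labels=[str(i) for i in range(k)],
            )
            ours = tc.multiclass_mcc(cm)
            assert ours == pytest.approx(_cov_form_mcc(actual, predicted, k), abs=1e-10)
            assert ours == pytest.approx(
                matthews_corrcoef(actual, predicted), abs=1e-10
            )
            assert -1.0 <= ours <= 1.0

    def test_invariant_under_simultaneous_label_permutation(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 20, size=(4, 4))
        cm = tc.ConfusionMatrix(labels=list("abcd"), counts=counts)
        perm = rng.permutation(4)
        cm_p = tc.ConfusionMatrix(
            labels=[cm.labels[i] for i in perm],
            counts=counts[np.ix_(perm, perm)],
        )
        assert tc.multiclass_mcc(cm) == pytest.approx(tc.multiclass_mcc(cm_p))


class TestSplitStats:
    def test_ick_split_row(self):
        vals = [100, 82.61, 86.95, 78.26, 82.61, 91.30, 82.61, 82.60]
        mean, sd = tc.split_stats(vals)
        assert mean == pytest.approx(85.87, abs=0.005)
        assert sd == pytest.approx(6.87, abs=0.005)

    def test_ktx_split_row(self):
        vals = [82.18, 89.52, 73.79, 77.78, 87.63, 78.41, 76.73, 71.07]
        mean, sd = tc.split_stats(vals)
        assert mean == pytest.approx(79.64, abs=0.005)
        assert sd == pytest.approx(6.43, abs=0.005)

    def test_constant_list(self):
        mean, sd = tc.split_stats([4.2] * 8)
        assert mean == pytest.approx(4.2) and sd == 0.0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(50, 100, size=8)
        m0, s0 = tc.split_stats(vals)
        m1, s1 = tc.split_stats(vals + 10)
        assert m1 == pytest.approx(m0 + 10)
        assert s1 == pytest.approx(s0)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            tc.split_stats([1.0])


class TestTwoSampleT:
    def test_identical_samples_give_zero_and_one(self):
        t, p = tc.two_sample_t([3, 3, 3], [3, 3, 3])
        assert t == 0.0 and p == 1.0

    def test_gross_separation_is_significant(self):
        t, p = tc.two_sample_t([1, 2, 3], [101, 102, 103])
        assert p < 0.01

    def test_matches_textbook_welch_formula_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = rng.normal(10, 3, size=int(rng.integers(3, 15)))
            b = rng.normal(12, 5, size=int(rng.integers(3, 15)))
            t, p = tc.two_sample_t(a, b)
            va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
            t_ref = (a.mean() - b.mean()) / math.sqrt(va + vb)
            df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
            p_ref = 2 * stats.t.sf(abs(t_ref), df)
            assert t == pytest.approx(t_ref, rel=1e-10)
            assert p == pytest.approx(p_ref, rel=1e-10)

    def test_paired_variant(self):
        a = [10.0, 12.0, 9.0, 14.0]
        b = [11.0, 13.0, 10.0, 15.0]
        t, p = tc.two_sample_t(a, b, paired=True)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            tc.two_sample_t([1.0], [1.0, 2.0])
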