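"""Statistics module: confusion-matrix orientation, report formulas against
brute-force and scikit-learn cross-checks, Pearson r, and the H&E/IHC
agreement analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as scipy_stats
from sklearn.metrics import precision_recall_fscore_support

from he2ihc.metrics import (
    agreement_analysis,
    classification_report,
    confusion_matrix,
    pearson_r,
)


def brute_force_confusion(actual, predicted, n=3):
    m = np.zeros((n, n), dtype=int)
    for a, p in zip(actual, predicted):
        m[a][p] += 1
    return m


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = [0] * 3 + [1] * 3 + [2] * 3
        cm = confusion_matrix(y, y)
        np.testing.assert_array_equal(cm.matrix, np.diag([3, 3, 3]))
        assert cm.accuracy == 1.0

    def test_rows_are_actual_columns_predicted(self):
        cm = confusion_matrix([0, 0, 1], [1, 0, 1])
        assert cm.matrix[0, 1] == 1  # actual 0 predicted 1
        assert cm.matrix[0, 0] == 1 and cm.matrix[1, 1] == 1

    def test_matches_brute_force_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 3, 50)
            p = rng.integers(0, 3, 50)
            np.testing.assert_array_equal(
                confusion_matrix(a, p).matrix, brute_force_confusion(a, p)
            )

    def test_marginals_and_micro_recall_identity(self):
        rng = np.random.default_rng(1)
        a, p = rng.integers(0, 3, 200), rng.integers(0, 3, 200)
        cm = confusion_matrix(a, p)
        np.testing.assert_array_equal(cm.supports, np.bincount(a, minlength=3))
        rep = classification_report(a, p)
        micro_recall = (np.diag(cm.matrix).sum()) / cm.total
        assert rep.accuracy == pytest.approx(micro_recall)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 1], [0])
        with pytest.raises(ValueError):
            confusion_matrix([0, 5], [0, 1])


class TestClassificationReport:
    def test_perfect_predictions_score_one_everywhere(self):
        y = [0, 1, 2] * 4
        rep = classification_report(y, y)
        np.testing.assert_array_equal(rep.precision, [1, 1, 1])
        np.testing.assert_array_equal(rep.recall, [1, 1, 1])
        np.testing.assert_array_equal(rep.f1, [1, 1, 1])
        assert rep.accuracy == 1.0

    def test_f1_is_harmonic_mean(self):
        # engineered case: precision = recall = 0.8 for class 0
        actual = [0] * 10 + [1] * 10
        predicted = [0] * 8 + [1] * 2 + [1] * 8 + [0] * 2
        rep = classification_report(actual, predicted)
        assert rep.precision[0] == pytest.approx(0.8)
        assert rep.recall[0] == pytest.approx(0.8)
        assert rep.f1[0] == pytest.approx(0.8)

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, p = rng.integers(0, 3, 80), rng.integers(0, 3, 80)
            rep = classification_report(a, p)
            prec, rec, f1, sup = precision_recall_fscore_support(
                a, p, labels=[0, 1, 2], zero_division=0
            )
            np.testing.assert_allclose(rep.precision, prec, atol=1e-12)
            np.testing.assert_allclose(rep.recall, rec, atol=1e-12)
            np.testing.assert_allclose(rep.f1, f1, atol=1e-12)
            np.testing.assert_array_equal(rep.support, sup)

    def test_zero_denominator_reports_zero_with_flag(self):
        rep = classification_report([0, 0, 1], [0, 0, 0])  # class 2 absent, 1 never predicted...
        assert rep.recall[2] == 0 and rep.zero_denominator[2]

    def test_report_frame_layout(self):
        rep = classification_report([0, 1, 2], [0, 1, 2])
        frame = rep.to_frame()
        assert list(frame.columns) == ["Precision", "Recall", "f1-score", "Support"]
        assert list(frame.index) == [
            "Negative", "Positive", "Background", "Macro avg", "Weighted avg",
        ]
        assert frame.loc["Macro avg", "Support"] == 3


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula_and_scipy(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.0, 4.0, 6.5])
        # direct evaluation of Cov(X,Y)/sqrt(Var X Var Y)
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        want = cov / np.sqrt(x.var() * y.var())
        assert pearson_r(x, y) == pytest.approx(want)
        assert pearson_r(x, y) == pytest.approx(scipy_stats.pearsonr(x, y)[0])

    def test_zero_variance_is_flagged_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(-100, 100), min_size=3, max_size=20),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_bounded_and_affine_invariant(self, xs, a, b):
        x = np.asarray(xs)
        rng = np.random.default_rng(11)
        y = rng.normal(size=len(x))
        if x.var() == 0 or y.var() == 0:
            return
        r = pearson_r(x, y)
        assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9
        assert pearson_r(a * x + b, y) == pytest.approx(r, abs=1e-6)


class TestAgreementAnalysis:
    @staticmethod
    def _table(he_vals, ihc_vals):
        rows = []
        for i, (h, c) in enumerate(zip(he_vals, ihc_vals)):
            for source, v in (("he", h), ("ihc", c)):
                rows.append(
                    {"roi_id": f"r{i}", "source": source,
                     "D_pos": v, "D_neg": 1 - v, "R_pos": v}
                )
        return pd.DataFrame(rows)

    def test_identical_quantities_correlate_perfectly(self):
        vals = np.linspace(0.1, 0.9, 8)
        out = agreement_analysis(self._table(vals, vals))
        for index in ("D_pos", "D_neg", "R_pos"):
            assert out["correlations"][index] == pytest.approx(1.0)

    def test_independent_pairs_show_no_correlation(self):
        rng = np.random.default_rng(3)
        out = agreement_analysis(self._table(rng.random(200), rng.random(200)))
        for r in out["correlations"].values():
            assert abs(r) < 0.2

    def test_histograms_count_all_rois(self):
        vals = np.linspace(0.0, 0.99, 10)
        out = agreement_analysis(self._table(vals, vals), n_bins=5)
        assert out["histograms"]["R_pos"]["he"]["counts"].sum() == 10

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            agreement_analysis(self._table([0.5], [0.5]))
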