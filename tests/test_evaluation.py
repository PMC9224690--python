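"""Fold plans, the metric panel, ROC, and cohort statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from camrad.evaluation import (
    MODALITY_COMBINATIONS,
    auc,
    chi_squared_test,
    cohort_stats,
    confusion_metrics,
    make_folds,
    roc_points,
    split_cohort,
    t_test_from_summary,
)
from oracles import bf_confusion

STUDY_LABELS = np.array([1] * 56 + [0] * 55)


class TestFolds:
    def test_study_cohort_split_is_89_22(self):
        train, val = split_cohort(STUDY_LABELS, 0.8, seed=0)
        assert len(train) == 89 and len(val) == 22
        assert set(train) | set(val) == set(range(111))

    def test_five_fold_partition_each_validates_once(self):
        plan = make_folds(STUDY_LABELS, k=5, seed=0)
        seen = np.concatenate([val for _, val in plan])
        assert sorted(seen) == list(range(111))
        for train, val in plan:
            assert len(val) in (22, 23)
            assert len(train) + len(val) == 111
            # train fraction 0.8 within one patient of exact
            assert abs(len(train) - 0.8 * 111) <= 1.0

    def test_stratification_balances_positives(self):
        plan = make_folds(STUDY_LABELS, k=5, seed=1)
        for _, val in plan:
            pos = STUDY_LABELS[val].sum()
            assert 11 <= pos <= 12

    def test_deterministic(self):
        a = make_folds(STUDY_LABELS, k=5, seed=3)
        b = make_folds(STUDY_LABELS, k=5, seed=3)
        for (ta, va), (tb, vb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(va, vb)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            make_folds(np.array([1, 1, 0, 0, 0, 0, 0]), k=3)
        with pytest.raises(ValueError, match="both classes"):
            make_folds(np.ones(10), k=2)


class TestAuc:
    def test_four_point_hand_example(self):
        assert auc([0, 0, 1, 1], [0.1, 0.4, 0.35, 0.8]) == pytest.approx(0.75)

    def test_perfect_and_null(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        assert auc(y, s) == pytest.approx(0.5, abs=0.03)

    def test_ties_count_half(self):
        assert auc([0, 1], [0.5, 0.5]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auc([1, 1], [0.2, 0.8])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1),
                              st.floats(0, 1, allow_nan=False)),
                    min_size=4, max_size=40))
    def test_complement_symmetry_and_sklearn_agreement(self, pairs):
        y = np.array([t for t, _ in pairs])
        s = np.array([v for _, v in pairs])
        if y.min() == y.max():
            return
        from sklearn.metrics import roc_auc_score

        a = auc(y, s)
        assert a == pytest.approx(roc_auc_score(y, s), abs=1e-12)
        if len(np.unique(s)) == len(s):  # tie-free
            assert a + auc(y, -s) == pytest.approx(1.0, abs=1e-12)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 0, 1], [0.1, 0.9, 0.2, 0.8])
        for k in ("acc", "f1", "sens", "spec", "ppv", "npv", "mcc"):
            assert m[k] == 1.0

    def test_hand_example_tp3_tn2_fp1(self):
        y = [1, 1, 1, 0, 0, 0]
        s = [0.9, 0.8, 0.7, 0.6, 0.2, 0.1]
        m = confusion_metrics(y, s, threshold=0.5)
        assert (m["tp"], m["tn"], m["fp"], m["fn"]) == (3, 2, 1, 0)
        assert m["sens"] == 1.0
        assert m["spec"] == pytest.approx(2 / 3)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["mcc"] == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_all_positive_predictor_degenerate(self):
        y = [0, 1] * 5
        s = [0.9] * 10
        m = confusion_metrics(y, s)
        assert m["sens"] == 1.0 and m["spec"] == 0.0 and m["mcc"] == 0.0

    def test_f1_is_harmonic_mean_of_ppv_sens(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        s = rng.random(50)
        m = confusion_metrics(y, s)
        if m["ppv"] > 0 and m["sens"] > 0:
            h = 2 * m["ppv"] * m["sens"] / (m["ppv"] + m["sens"])
            assert m["f1"] == pytest.approx(h)

    def test_brute_force_oracle_many_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            y = rng.integers(0, 2, n)
            s = rng.random(n)
            m = confusion_metrics(y, s)
            tp, fp, tn, fn = bf_confusion(y, (s >= 0.5).astype(int))
            assert (m["tp"], m["fp"], m["tn"], m["fn"]) == (tp, fp, tn, fn)
            assert m["acc"] == pytest.approx((tp + tn) / n)
            den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            expected_mcc = 0.0 if den == 0 else (tp * tn - fp * fn) / den
            assert m["mcc"] == pytest.approx(expected_mcc)

    def test_threshold_bounds(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [0.2, 0.8], threshold=1.0)


class TestRoc:
    def test_endpoints_and_perfect_corner(self):
        pts = roc_points([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert any((f == 0.0 and t == 1.0) for f, t in pts)

    def test_anti_perfect_passes_through_1_0(self):
        pts = roc_points([1, 1, 0, 0], [0.1, 0.2, 0.8, 0.9])
        assert any((f == 1.0 and t == 0.0) for f, t in pts)

    def test_trapezoid_area_equals_auc(self):
        y = [0, 0, 1, 1]
        s = [0.1, 0.4, 0.35, 0.8]
        pts = roc_points(y, s)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(auc(y, s), abs=1e-12)

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(3)
        pts = roc_points(rng.integers(0, 2, 50), rng.random(50))
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()


class TestCohortStats:
    def test_identical_groups_null(self):
        counts = [[20, 20], [15, 15]]
        stat, p = chi_squared_test(counts)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        t, _ = t_test_from_summary(5.0, 1.0, 30, 5.0, 1.0, 30)
        assert t == pytest.approx(0.0)

    def test_study_sex_table_brackets_published_p(self):
        """26M/30F vs 36M/19F: p(Pearson)=0.044, p(Yates)=0.068 bracket the
        published 0.056; the continuity-correction choice is unstated."""
        tab = [[26, 36], [30, 19]]
        _, p_plain = chi_squared_test(tab, correction=False)
        _, p_corr = chi_squared_test(tab, correction=True)
        assert p_plain == pytest.approx(0.0436, abs=0.001)
        assert p_corr == pytest.approx(0.0677, abs=0.001)
        assert p_plain < 0.056 < p_corr

    def test_study_age_t_test(self):
        _, p = t_test_from_summary(53.45, 13.61, 56, 55.85, 13.18, 55)
        assert p == pytest.approx(0.346, abs=0.005)

    def test_study_tumor_type_chi_squared(self):
        tt = [[25, 40], [2, 4], [13, 7], [5, 4], [11, 0]]
        _, p = chi_squared_test(tt, correction=False)
        assert p == pytest.approx(0.002, abs=5e-4)

    def test_cohort_stats_frame(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "label": rng.integers(0, 2, 60),
            "sex": rng.choice(["M", "F"], 60),
            "tumor_type": rng.choice(["GBM", "DA", "O"], 60),
            "age": rng.normal(55, 12, 60),
        })
        out = cohort_stats(df)
        assert list(out["parameter"]) == ["sex", "tumor_type", "age"]
        assert ((out["p_value"] >= 0) & (out["p_value"] <= 1)).all()


def test_modality_combination_layout():
    sizes = [len(c) for c in MODALITY_COMBINATIONS]
    assert sizes == [1] * 4 + [2] * 6 + [3] * 4 + [4]
    assert len(set(MODALITY_COMBINATIONS)) == 15
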