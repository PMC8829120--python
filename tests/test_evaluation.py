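import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test as lifelines_logrank
from scipy import stats

from mimrda.evaluation import (
    compare_auc,
    compare_rankings,
    km_curve,
    logrank_test,
    median_split,
    rf_evaluate,
    survival_for_mirna,
    topk_overlap_percentage,
)
from mimrda.io_formats import (
    DegenerateDataError,
    LabelSet,
    SampleMetadata,
    ValidationError,
)
from mimrda.synthetic_data import simulate_survival

from .conftest import make_expr, make_two_group_meta


class TestTopkOverlap:
    def test_nine_of_ten_is_ninety_percent(self):
        ranked = [f"mir{i}" for i in range(20)]
        labels = LabelSet(mirna_ids=frozenset(ranked[:9] + ["other"]))
        assert topk_overlap_percentage(ranked, labels, 10) == 90.0

    def test_disjoint_labels_zero(self):
        labels = LabelSet(mirna_ids=frozenset({"x"}))
        assert topk_overlap_percentage(["a", "b"], labels, 2) == 0.0

    def test_superset_labels_hundred(self):
        labels = LabelSet(mirna_ids=frozenset("abc"))
        assert topk_overlap_percentage(["a", "b"], labels, 2) == 100.0

    def test_k_validation(self):
        labels = LabelSet(mirna_ids=frozenset({"a"}))
        with pytest.raises(ValidationError):
            topk_overlap_percentage(["a"], labels, 0)
        with pytest.raises(ValidationError):
            topk_overlap_percentage(["a"], labels, 2)

    def test_monotone_in_label_set(self):
        ranked = [f"mir{i}" for i in range(10)]
        small = LabelSet(mirna_ids=frozenset(ranked[:2]))
        large = LabelSet(mirna_ids=frozenset(ranked[:5]))
        assert (topk_overlap_percentage(ranked, small, 5)
                <= topk_overlap_percentage(ranked, large, 5))


class TestCompareRankings:
    def test_identical_rankings_identical_counts(self):
        r = [f"mir{i}" for i in range(10)]
        labels = LabelSet(mirna_ids=frozenset(r[:4]))
        counts = compare_rankings(r, r, r, labels, n=5)
        assert counts == {"p_g": 4, "p_mirna": 4, "p_nde": 4}

    def test_all_labeled_scores_n(self):
        r = [f"mir{i}" for i in range(10)]
        labels = LabelSet(mirna_ids=frozenset(r))
        counts = compare_rankings(r, r[::-1], r, labels, n=6)
        assert set(counts.values()) == {6}

    def test_mismatched_mirna_sets_rejected(self):
        labels = LabelSet(mirna_ids=frozenset({"a"}))
        with pytest.raises(ValidationError):
            compare_rankings(["a", "b"], ["a", "c"], ["a", "b"], labels)

    def test_combined_ranking_flags_at_least_as_many_planted(self):
        """The P_G top-n captures at least as many planted disease miRNAs
        as the DE-only ranking in every seeded replicate."""
        from mimrda import PRESET, run_pipeline, simulate_dataset
        wins = 0
        n_reps = 20
        for seed in range(200, 200 + n_reps):
            mrna, mirna, meta, inter, truth = simulate_dataset(PRESET, seed)
            scores, _ = run_pipeline(mrna, mirna, meta, inter)
            labels = LabelSet(mirna_ids=frozenset(truth.disease_mirnas))
            pg = scores["mirna_id"].tolist()
            pm = scores.sort_values(["p_mirna", "mirna_id"])["mirna_id"].tolist()
            pn = scores.sort_values(["p_nde", "mirna_id"])["mirna_id"].tolist()
            counts = compare_rankings(pg, pm, pn, labels, n=25)
            wins += counts["p_g"] >= counts["p_mirna"]
        assert wins >= int(0.95 * n_reps), wins


class TestMedianSplit:
    def test_even_split(self):
        s = median_split(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert set(s[s == "high"].index) == {"c", "d"}

    def test_between_tied_values(self):
        s = median_split(pd.Series([1, 1, 2, 2], index=list("abcd")))
        assert set(s[s == "high"].index) == {"c", "d"}

    def test_ties_at_median_go_low(self):
        s = median_split(pd.Series([1, 1, 1, 2], index=list("abcd")))
        assert set(s[s == "high"].index) == {"d"}
        assert (s[list("abc")] == "low").all()

    def test_degenerate_and_small_inputs_rejected(self):
        with pytest.raises(DegenerateDataError):
            median_split(pd.Series([2, 2, 2, 2]))
        with pytest.raises(ValidationError):
            median_split(pd.Series([1, 2, 3]))


class TestKMCurve:
    def test_hand_product_limit(self):
        s = km_curve([1, 2, 3], [True, True, True])
        assert s.loc[1] == pytest.approx(2 / 3)
        assert s.loc[2] == pytest.approx(1 / 3)
        assert s.loc[3] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        s = km_curve([5, 8, 12], [False, False, False])
        assert (s == 1.0).all()

    def test_single_subject(self):
        s = km_curve([5], [True])
        assert s.loc[5] == 0.0

    def test_order_invariance_and_monotonicity(self):
        t = [3, 1, 4, 1, 5, 9, 2, 6]
        e = [1, 0, 1, 1, 0, 1, 1, 0]
        s1 = km_curve(t, e)
        perm = np.random.default_rng(0).permutation(len(t))
        s2 = km_curve(np.array(t)[perm], np.array(e)[perm])
        pd.testing.assert_series_equal(s1, s2)
        assert (np.diff(s1.values) <= 1e-12).all()
        assert s1.iloc[0] <= 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_curve([], [])


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3], [True, True, True]
        chi2, p, hr = logrank_test(t, e, t, e)
        assert chi2 == 0.0 and p == 1.0 and hr == 1.0

    def test_hand_computed_alternating_example(self):
        # high events at 1,3,5; low at 2,4,6; O/E accumulated by hand:
        # E_high = 1/2+2/5+1/2+1/3+1/2 = 67/30, V = 1091/900
        # chi2 = (3 - 67/30)^2 / (1091/900) = 529/1091
        chi2, p, hr = logrank_test([1, 3, 5], [1, 1, 1], [2, 4, 6], [1, 1, 1])
        assert chi2 == pytest.approx(529 / 1091, abs=1e-10)
        assert p == pytest.approx(stats.chi2.sf(529 / 1091, 1), abs=1e-12)
        assert hr == pytest.approx((3 / (67 / 30)) / (3 / (113 / 30)), abs=1e-10)

    def test_symmetry_inverts_hr(self):
        rng = np.random.default_rng(8)
        t1, t2 = rng.exponential(1, 30), rng.exponential(2, 25)
        e1 = rng.uniform(size=30) < 0.8
        e2 = rng.uniform(size=25) < 0.8
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t2, e2, t1, e1)
        assert a[0] == pytest.approx(b[0], abs=1e-12)
        assert a[1] == pytest.approx(b[1], abs=1e-12)
        assert a[2] == pytest.approx(1 / b[2], rel=1e-12)

    def test_matches_lifelines_chi2(self):
        rng = np.random.default_rng(9)
        t1, t2 = rng.exponential(1, 40), rng.exponential(1.8, 35)
        e1 = rng.uniform(size=40) < 0.7
        e2 = rng.uniform(size=35) < 0.7
        chi2, p, _ = logrank_test(t1, e1, t2, e2)
        ref = lifelines_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
        assert chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_no_events_rejected(self):
        with pytest.raises(DegenerateDataError):
            logrank_test([1, 2], [False, False], [3], [False])
        with pytest.raises(ValidationError):
            logrank_test([], [], [1], [True])


class TestSurvivalForMirna:
    def _study(self, hr=0.3, seed=0):
        meta = simulate_survival(200, hr=hr, median_low_group=365,
                                 censor_rate=0.2, seed=seed)
        # expression tracks the high/low split with noise
        rng = np.random.default_rng(seed + 1)
        base = np.where(meta.table["split"] == "high", 10.0, 6.0)
        values = base + rng.normal(0, 0.5, size=len(base))
        expr = make_expr(values[None, :], meta, kind="miRNA")
        return expr, meta

    def test_detects_protective_mirna(self):
        expr, meta = self._study(hr=0.3)
        res = survival_for_mirna("f0", expr, meta)
        assert res.hr < 1.0
        assert res.logrank_p < 0.05
        assert res.n_high + res.n_low == 200

    def test_requires_survival_metadata(self):
        meta = make_two_group_meta(3, 3)
        expr = make_expr(np.arange(6, dtype=float)[None, :], meta, kind="miRNA")
        with pytest.raises(ValidationError):
            survival_for_mirna("f0", expr, meta)


class TestRFEvaluate:
    def _data(self, n_feat=15, n=40, signal=True, seed=0):
        rng = np.random.default_rng(seed)
        meta = make_two_group_meta(n // 2, n // 2)
        values = rng.normal(8, 1, size=(n_feat, n))
        if signal:
            values[:5, :n // 2] += 2.0
        return make_expr(values, meta, kind="miRNA"), meta

    def test_same_seed_identical_aucs(self):
        expr, meta = self._data()
        feats = [f"f{i}" for i in range(5)]
        a = rf_evaluate(expr, meta, feats, n_reps=3, seed=5, n_estimators=20)
        b = rf_evaluate(expr, meta, feats, n_reps=3, seed=5, n_estimators=20)
        assert np.array_equal(a, b)

    def test_informative_features_beat_noise(self):
        expr, meta = self._data(seed=2)
        good = rf_evaluate(expr, meta, [f"f{i}" for i in range(5)],
                           n_reps=5, seed=1, n_estimators=30)
        noise = rf_evaluate(expr, meta, [f"f{i}" for i in range(10, 15)],
                            n_reps=5, seed=1, n_estimators=30)
        assert good.mean() > 0.9 > noise.mean()

    def test_small_class_rejected(self):
        expr, meta = self._data(n=8)
        with pytest.raises(ValidationError):
            rf_evaluate(expr, meta, ["f0"], folds=5, n_reps=1, seed=0)

    def test_unmeasured_feature_rejected(self):
        expr, meta = self._data()
        with pytest.raises(ValidationError):
            rf_evaluate(expr, meta, ["nope"], n_reps=1, seed=0)


class TestCompareAUC:
    def test_identical_lists_p_one(self):
        a = np.full(20, 0.8)
        assert compare_auc(a, a.copy()).p_value == 1.0

    def test_clear_separation_significant(self):
        rng = np.random.default_rng(3)
        top = 0.95 + rng.normal(0, 0.01, 100)
        rand = 0.50 + rng.normal(0, 0.01, 100)
        assert compare_auc(top, rand, k=10).p_value < 1e-3

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(size=30), rng.uniform(size=30)
        assert compare_auc(a, b).p_value == pytest.approx(
            compare_auc(b, a).p_value, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_auc(np.ones(3), np.ones(4))
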