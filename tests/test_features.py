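"""Feature scaling, class weighting, metrics and distribution statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from neoimm.features import (
    DegenerateRangeError,
    EmptyClassError,
    apply_minmax,
    auroc,
    binary_metrics,
    class_weights,
    compare_distributions,
    fit_minmax,
    pearson_correlation,
    significance_stars,
    threshold_binding,
)


class TestMinMax:
    def test_fit_stores_extrema(self):
        c = fit_minmax([0.0, 5.0, 10.0])
        assert (c.x_min, c.x_max) == (0.0, 10.0)
        c = fit_minmax([-1.0, 1.0])
        assert (c.x_min, c.x_max) == (-1.0, 1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateRangeError):
            fit_minmax([500.0])
        with pytest.raises(DegenerateRangeError):
            fit_minmax([3.0, 3.0, 3.0])

    def test_endpoints_map_to_unit_interval(self):
        c = fit_minmax([2.0, 4.0, 8.0])
        assert apply_minmax(2.0, c) == 0.0
        assert apply_minmax(8.0, c) == 1.0

    def test_direct_substitution(self):
        c = fit_minmax([0.0, 10.0])
        assert apply_minmax(2.5, c) == pytest.approx(0.25)

    def test_out_of_range_clamped(self):
        c = fit_minmax([0.0, 10.0])
        assert apply_minmax(-5.0, c) == 0.0
        assert apply_minmax(50.0, c) == 1.0

    def test_log10_transform_linearizes_decades(self):
        c = fit_minmax([1.0, 10_000.0], transform="log10")
        assert apply_minmax(100.0, c) == pytest.approx(0.5)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50, unique=True),
           st.floats(-1e6, 1e6), st.floats(-1e6, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_monotone_non_decreasing(self, values, x1, x2):
        c = fit_minmax(values)
        lo, hi = sorted((x1, x2))
        assert apply_minmax(lo, c) <= apply_minmax(hi, c)


class TestClassWeights:
    def test_balanced_classes_unit_weights(self):
        cw = class_weights(50, 50)
        assert cw.w_pos == cw.w_neg == 1.0

    def test_imbalanced_direct_substitution(self):
        cw = class_weights(25, 75)
        assert cw.w_pos == pytest.approx(2.0)
        assert cw.w_neg == pytest.approx(2.0 / 3.0)
        assert cw.w_pos * cw.s_pos + cw.w_neg * cw.s_neg == pytest.approx(100)

    def test_empty_class_rejected(self):
        with pytest.raises(EmptyClassError):
            class_weights(0, 10)

    @given(st.integers(1, 10_000), st.integers(1, 10_000))
    @settings(max_examples=1000, deadline=None)
    def test_weighted_mass_equals_total(self, s_pos, s_neg):
        cw = class_weights(s_pos, s_neg)
        total = s_pos + s_neg
        assert cw.w_pos == pytest.approx((1 / s_pos) * (total / 2))
        assert cw.w_neg == pytest.approx((1 / s_neg) * (total / 2))
        assert cw.w_pos * s_pos + cw.w_neg * s_neg == pytest.approx(total)


class TestBinaryMetrics:
    def test_perfect_predictor(self):
        acc, prec, rec = binary_metrics([True, False, True], [True, False, True])
        assert (acc, prec, rec) == (1.0, 1.0, 1.0)

    def test_all_negative_predictions(self):
        acc, prec, rec = binary_metrics([False] * 4, [True, True, False, False])
        assert prec is None
        assert rec == 0.0

    def test_hand_counted_confusion(self):
        # TP=3 FP=1 FN=2 TN=4
        pred = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        act = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        acc, prec, rec = binary_metrics(np.array(pred, bool), np.array(act, bool))
        assert acc == pytest.approx(0.7)
        assert prec == pytest.approx(0.75)
        assert rec == pytest.approx(0.6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            binary_metrics([True], [True, False])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1,
                    max_size=200))
    @settings(max_examples=100, deadline=None)
    def test_agrees_with_sklearn(self, pairs):
        from sklearn.metrics import accuracy_score, precision_score, recall_score
        pred = np.array([p for p, _ in pairs])
        act = np.array([a for _, a in pairs])
        acc, prec, rec = binary_metrics(pred, act)
        assert acc == pytest.approx(accuracy_score(act, pred))
        if prec is not None:
            assert prec == pytest.approx(precision_score(act, pred,
                                                         zero_division=0))
        if rec is not None:
            assert rec == pytest.approx(recall_score(act, pred, zero_division=0))


class TestThresholdBinding:
    @pytest.mark.parametrize("ic50,pct,expected", [
        (499.0, 0.5, True),
        (500.0, 0.5, False),   # IC50 boundary is strict
        (100.0, 2.0, False),   # percentile fails
        (100.0, 1.0, False),   # percentile boundary is strict
        (0.0, 0.0, True),
    ])
    def test_strict_inequalities(self, ic50, pct, expected):
        assert threshold_binding(ic50, pct) is expected


class TestCompareDistributions:
    def test_identical_groups_not_significant(self):
        vals = list(range(30))
        _, p, stars = compare_distributions(vals, vals)
        assert p > 0.05
        assert stars == "ns"

    def test_fully_separated_groups_four_stars(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 0.01, 50)
        b = rng.normal(1.0, 0.01, 50)
        _, p, stars = compare_distributions(a, b)
        assert p < 1e-4
        assert stars == "****"

    def test_agrees_with_permutation_oracle(self):
        """Brute-force permutation of the rank-sum statistic at n=20."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 20)
        stat, p, _ = compare_distributions(a, b)
        pooled = np.concatenate([a, b])
        n_extreme = 0
        n_draws = 10_000
        observed = abs(stat - len(a) * len(b) / 2)
        for _ in range(n_draws):
            rng.shuffle(pooled)
            s = stats.mannwhitneyu(pooled[:20], pooled[20:],
                                   alternative="two-sided").statistic
            if abs(s - len(a) * len(b) / 2) >= observed:
                n_extreme += 1
        p_perm = n_extreme / n_draws
        assert p == pytest.approx(p_perm, abs=3 * np.sqrt(p_perm * (1 - p_perm)
                                                          / n_draws) + 1e-3)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions([1.0], [2.0, 3.0])


class TestSignificanceStars:
    @pytest.mark.parametrize("p,stars", [
        (5e-5, "****"), (5e-4, "***"), (5e-3, "**"), (0.03, "*"), (0.2, "ns"),
    ])
    def test_tiers(self, p, stars):
        assert significance_stars(p) == stars


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_data_small_r(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        r, p = pearson_correlation(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateRangeError):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAuroc:
    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(3)
        scores = rng.random(200)
        labels = rng.random(200) < 0.4
        assert auroc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(EmptyClassError):
            auroc([0.1, 0.9], [1, 1])
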