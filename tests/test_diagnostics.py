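"""ROC/AUC, optimal cutpoint, confusion metrics, McNemar and bootstrap inference."""

import numpy as np
import pytest

from visualscore.diagnostics import (
    auc_mann_whitney,
    bootstrap_ci,
    bootstrap_compare_auc,
    confusion_metrics,
    mcnemar_paired,
    optimal_cutpoint_roc01,
    roc_and_auc,
)
from visualscore.exceptions import SingleClassError


class TestRocAndAuc:
    def test_perfect_separation_gives_auc_one(self):
        assert roc_and_auc([1, 2, 3, 4], [0, 0, 1, 1]).auc == 1.0

    def test_constant_scores_give_auc_half(self):
        assert roc_and_auc([5, 5, 5, 5], [0, 1, 0, 1]).auc == pytest.approx(0.5)

    def test_hand_enumerated_pairs(self):
        # pos {4, 2} vs neg {1, 3}: 3 concordant of 4 pairs
        assert roc_and_auc([1, 4, 2, 3], [0, 1, 1, 0]).auc == pytest.approx(0.75)

    def test_single_class_is_an_error(self):
        with pytest.raises(SingleClassError):
            roc_and_auc([1, 2, 3], [1, 1, 1])

    def test_curve_is_monotone_and_anchored(self, rng):
        s = rng.normal(size=80)
        y = (rng.random(80) < 0.4).astype(int)
        roc = roc_and_auc(s, y)
        assert roc.sensitivity[0] == 0.0 and roc.specificity[0] == 1.0
        assert roc.sensitivity[-1] == 1.0
        assert np.all(np.diff(roc.sensitivity) >= 0)
        assert np.all(np.diff(1 - roc.specificity) >= 0)
        assert roc.n_pos + roc.n_neg == 80

    def test_trapezoid_equals_mann_whitney_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            s = rng.integers(0, 8, size=n).astype(float)  # heavy ties
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            assert roc_and_auc(s, y).auc == pytest.approx(auc_mann_whitney(s, y), abs=1e-12)

    def test_label_swap_maps_auc_to_its_complement(self, rng):
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert roc_and_auc(s, 1 - y).auc == pytest.approx(1 - roc_and_auc(s, y).auc, abs=1e-12)


def brute_force_roc01(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    best = None
    for t in sorted(set(s)):
        pred = s >= t
        sens = (pred & (y == 1)).sum() / (y == 1).sum()
        spec = (~pred & (y == 0)).sum() / (y == 0).sum()
        d = np.hypot(1 - sens, 1 - spec)
        key = (d, -sens, t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


class TestOptimalCutpoint:
    def test_perfectly_separated_data(self):
        cut, m = optimal_cutpoint_roc01([1, 2, 8, 9], [0, 0, 1, 1])
        assert cut == 8.0
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_agrees_with_brute_force_on_spec_instance(self):
        s, y = [1, 2, 3, 4, 5, 6], [0, 0, 1, 0, 1, 1]
        cut, _ = optimal_cutpoint_roc01(s, y)
        assert cut == brute_force_roc01(s, y)

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 60))
            s = rng.integers(0, 10, size=n).astype(float)
            y = (rng.random(n) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            cut, _ = optimal_cutpoint_roc01(s, y)
            assert cut == brute_force_roc01(s, y)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        m = confusion_metrics([0, 1, 0, 1], [0, 1, 0, 1])
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_printed_operating_point_arithmetic(self):
        # TP 17, FN 3, TN 12, FP 8 -> sens 85%, spec 60%
        y = [1] * 20 + [0] * 20
        pred = [1] * 17 + [0] * 3 + [1] * 8 + [0] * 12
        m = confusion_metrics(pred, y)
        assert m.sensitivity == pytest.approx(0.85)
        assert m.specificity == pytest.approx(0.60)

    def test_zero_denominator_is_flagged_not_silent_zero(self):
        m = confusion_metrics([0, 0, 0, 0], [0, 1, 0, 1])
        assert np.isnan(m.ppv) and "ppv" in m.undefined

    def test_complement_identities(self, rng):
        y = (rng.random(50) < 0.5).astype(int)
        y[0], y[1] = 0, 1
        pred = (rng.random(50) < 0.5).astype(int)
        m = confusion_metrics(pred, y)
        fnr = m.fn / (m.fn + m.tp)
        fpr = m.fp / (m.fp + m.tn)
        assert m.sensitivity + fnr == pytest.approx(1.0)
        assert m.specificity + fpr == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion_metrics([0, 1], [0, 1, 1])


class TestMcNemar:
    def test_symmetric_discordance_gives_p_one(self):
        # b = c = 5: construct 10 true positives, 5 caught only by each classifier
        y = np.ones(10, dtype=int)
        p1 = np.array([1] * 5 + [0] * 5)
        p2 = np.array([0] * 5 + [1] * 5)
        res = mcnemar_paired(p1, p2, y, "positives")
        assert (res.b, res.c) == (5, 5)
        assert res.p_value == pytest.approx(1.0)
        assert res.method == "exact"

    def test_one_sided_discordance_exact_binomial_tail(self):
        y = np.ones(12, dtype=int)
        p1 = np.array([1] * 10 + [0] * 2)
        p2 = np.zeros(12, dtype=int)
        res = mcnemar_paired(p1, p2, y, "positives")
        assert (res.b, res.c) == (10, 0)
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_identical_classifiers_flagged_zero_discordance(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([1, 0, 0, 1])
        res = mcnemar_paired(p, p, y, "negatives")
        assert res.zero_discordance and res.p_value == 1.0

    def test_large_discordance_switches_to_chi_square(self):
        y = np.ones(40, dtype=int)
        p1 = np.array([1] * 20 + [0] * 20)
        p2 = np.array([0] * 15 + [1] * 25)
        res = mcnemar_paired(p1, p2, y, "positives")
        assert res.b + res.c >= 25 and res.method == "chi2_cc"
        assert 0 < res.p_value <= 1

    def test_specificity_restriction_uses_true_negatives(self):
        y = np.array([0, 0, 0, 1, 1])
        p1 = np.array([0, 1, 0, 1, 1])  # correct on negatives 0 and 2
        p2 = np.array([1, 0, 0, 1, 1])  # correct on negatives 1 and 2
        res = mcnemar_paired(p1, p2, y, "negatives")
        assert (res.b, res.c) == (1, 1)


class TestBootstrap:
    def test_constant_metric_zero_width_interval(self):
        lo, hi = bootstrap_ci(lambda x: 3.14, (np.arange(30),), B=200, seed=5)
        assert lo == hi == 3.14

    def test_deterministic_under_fixed_seed(self):
        data = (np.arange(25, dtype=float),)
        assert bootstrap_ci(np.mean, data, B=300, seed=9) == bootstrap_ci(np.mean, data, B=300, seed=9)

    def test_sensitivity_upper_bound_reaches_one_on_few_positives(self):
        # 6 positives, 5 detected: resamples frequently contain only detected ones
        y = np.array([1] * 6 + [0] * 14)
        pred = np.array([1] * 5 + [0] * 1 + [0] * 14)

        def sens(p_, y_):
            from visualscore.diagnostics import confusion_metrics

            return confusion_metrics(p_, y_).sensitivity

        lo, hi = bootstrap_ci(sens, (pred, y), B=500, seed=3)
        assert hi == 1.0 and lo < 1.0

    def test_minimum_replicates_enforced(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, (np.arange(10),), B=50, seed=1)


class TestBootstrapCompareAuc:
    def test_identical_scores_give_null_comparison(self, rng):
        s = rng.normal(size=40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        res = bootstrap_compare_auc(s, s, y, B=200, seed=2)
        assert res.auc_diff == 0.0
        assert res.ci[0] <= 0.0 <= res.ci[1]
        assert res.p_value == 1.0

    def test_reproducible_under_fixed_seed(self, rng):
        s1, s2 = rng.normal(size=30), rng.normal(size=30)
        y = np.array([0, 1] * 15)
        a = bootstrap_compare_auc(s1, s2, y, B=150, seed=7)
        b = bootstrap_compare_auc(s1, s2, y, B=150, seed=7)
        assert a.ci == b.ci and a.p_value == b.p_value

    def test_null_rejection_rate_near_nominal(self):
        # two exchangeable scores: population delta-AUC is zero
        rng = np.random.default_rng(42)
        rej = n_done = 0
        for _ in range(500):
            s1, s2 = rng.standard_normal(50), rng.standard_normal(50)
            y = (rng.random(50) < 0.5).astype(int)
            if y.min() == y.max():
                continue
            res = bootstrap_compare_auc(s1, s2, y, B=200, seed=int(rng.integers(2**31)))
            rej += res.p_value < 0.05
            n_done += 1
        assert 0.03 <= rej / n_done <= 0.07
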