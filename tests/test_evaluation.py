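"""Discrimination, calibration, decision curves and cohort statistics."""

import numpy as np
import pytest

from dwirad.evaluation import (
    auc_mann_whitney,
    calibration_curve,
    chi_square_2x2,
    decision_curve,
    delong_ci,
    delong_paired_test,
    delong_variance,
    operating_point,
    percent,
    two_sample_t,
    youden_cutoff,
)


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        scores = np.concatenate([np.zeros(5), np.ones(5)])
        labels = np.array([0] * 5 + [1] * 5)
        assert auc_mann_whitney(scores, labels) == 1.0

    def test_all_ties(self):
        assert auc_mann_whitney(np.ones(10), np.array([0, 1] * 5)) == 0.5

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.normal(0, 1, 30), 1)  # rounding induces ties
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert auc_mann_whitney(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    def test_invariant_under_increasing_transforms(self, rng):
        scores = rng.normal(0, 1, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        base = auc_mann_whitney(scores, labels)
        assert auc_mann_whitney(np.exp(scores), labels) == pytest.approx(base)
        assert auc_mann_whitney(3 * scores + 7, labels) == pytest.approx(base)


class TestDelong:
    def test_duplicated_dataset_halves_variance(self, rng):
        scores = rng.normal(0, 1, 100)
        labels = np.array([0, 1] * 50)
        scores[labels == 1] += 1.0
        v1 = delong_variance(scores, labels)
        v2 = delong_variance(np.tile(scores, 2), np.tile(labels, 2))
        assert v2 == pytest.approx(v1 / 2, rel=0.25)

    def test_perfect_separation_degenerate_flag(self):
        scores = np.concatenate([np.zeros(10), np.ones(10)])
        labels = np.array([0] * 10 + [1] * 10)
        auc, lo, hi, degenerate = delong_ci(scores, labels)
        assert auc == 1.0 and degenerate

    def test_self_comparison_p_one(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        auc_a, auc_b, z, p = delong_paired_test(scores, scores, labels)
        assert (z, p) == (0.0, 1.0)

    def test_monotone_transform_p_one(self, rng):
        scores = rng.normal(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        *_, p = delong_paired_test(scores, np.exp(scores), labels)
        assert p == 1.0

    def test_mismatched_cases_rejected(self, rng):
        with pytest.raises(ValueError):
            delong_paired_test(np.ones(10), np.ones(11), np.ones(10))


class TestOperatingPoint:
    def test_perfect_classifier(self):
        scores = np.concatenate([np.zeros(8), np.ones(8)])
        labels = np.array([0] * 8 + [1] * 8)
        report = operating_point(scores, labels, n_bootstrap=100, seed=0)
        assert report.sensitivity == report.specificity == report.accuracy == 1.0

    def test_cutoff_matches_exhaustive_search(self, rng):
        scores = rng.normal(0, 1, 50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        cutoff = youden_cutoff(scores, labels)
        uniq = np.unique(scores)
        candidates = np.concatenate([[uniq[0] - 1], (uniq[:-1] + uniq[1:]) / 2,
                                     [uniq[-1] + 1]])
        best_j, best_c = -np.inf, None
        for c in candidates:
            pred = scores >= c
            sens = (pred & (labels == 1)).sum() / (labels == 1).sum()
            spec = (~pred & (labels == 0)).sum() / (labels == 0).sum()
            if sens + spec - 1 > best_j + 1e-12:
                best_j, best_c = sens + spec - 1, c
        assert cutoff == pytest.approx(best_c)

    def test_accuracy_from_confusion_matrix(self, rng):
        scores = rng.normal(0, 1, 80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        report = operating_point(scores, labels, n_bootstrap=50, seed=1)
        pred = scores >= report.cutoff
        tp = (pred & (labels == 1)).sum()
        tn = (~pred & (labels == 0)).sum()
        assert report.accuracy == pytest.approx((tp + tn) / 80)
        assert report.auc_ci[0] <= report.auc <= report.auc_ci[1]


class TestCalibration:
    def test_well_calibrated_simulation(self, rng):
        probs = rng.uniform(0.05, 0.95, 20_000)
        labels = (rng.random(20_000) < probs).astype(int)
        grouped, _ = calibration_curve(probs, labels)
        assert (grouped["observed"] - grouped["predicted"]).abs().max() < 0.05

    def test_constant_probability_single_point(self):
        labels = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        probs = np.full(10, 0.5)
        grouped, _ = calibration_curve(probs, labels)
        assert len(grouped) == 1
        assert grouped["predicted"].iloc[0] == pytest.approx(0.5)
        assert grouped["observed"].iloc[0] == pytest.approx(0.5)

    def test_anticalibrated_detected(self, rng):
        labels = rng.integers(0, 2, 2000)
        probs = np.clip(1.0 - labels + rng.normal(0, 0.05, 2000), 0, 1)
        grouped, _ = calibration_curve(probs, labels)
        lowest = grouped.iloc[0]  # lowest predicted decile
        highest = grouped.iloc[-1]
        assert lowest["observed"] > 0.9 and highest["observed"] < 0.1


class TestDecisionCurve:
    def test_treat_all_crosses_zero_at_prevalence(self, rng):
        labels = np.array([1] * 30 + [0] * 70)
        probs = rng.uniform(0, 1, 100)
        curve = decision_curve(probs, labels, thresholds=np.array([0.3]))
        assert curve.net_benefit_all[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_confusion_matrix_oracle(self, rng):
        probs = rng.uniform(0, 1, 60)
        labels = rng.integers(0, 2, 60)
        thresholds = np.array([0.1, 0.25, 0.5, 0.75, 0.9])
        curve = decision_curve(probs, labels, thresholds)
        n = len(labels)
        for i, t in enumerate(thresholds):
            tp = ((probs >= t) & (labels == 1)).sum()
            fp = ((probs >= t) & (labels == 0)).sum()
            expected = tp / n - fp / n * t / (1 - t)
            assert curve.net_benefit_model[i] == pytest.approx(expected, abs=1e-12)
        assert (curve.net_benefit_none == 0).all()

    def test_model_bounded_by_perfect_classifier(self, rng):
        labels = rng.integers(0, 2, 200)
        probs = rng.uniform(0, 1, 200)
        grid = np.arange(0.05, 1.0, 0.05)
        model = decision_curve(probs, labels, grid)
        perfect = decision_curve(labels.astype(float), labels, grid)
        assert (model.net_benefit_model <= perfect.net_benefit_model + 1e-12).all()

    def test_grid_bounds_rejected(self, rng):
        probs = rng.uniform(0, 1, 20)
        labels = rng.integers(0, 2, 20)
        with pytest.raises(ValueError):
            decision_curve(probs, labels, np.array([0.0, 0.5]))


class TestCohortStatistics:
    def test_cohort_split_chi_square_reproduces_printed_p(self):
        """Positive rates 75/167 vs 22/56: chi-square without continuity
        correction gives p = 0.463."""
        chi2, p = chi_square_2x2(75, 92, 22, 34)
        assert p == pytest.approx(0.463, abs=0.001)

    def test_proportional_rows_independent(self):
        chi2, p = chi_square_2x2(10, 20, 30, 60)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_expected_count_oracle(self, rng):
        a, b, c, d = rng.integers(5, 50, 4)
        chi2, _ = chi_square_2x2(a, b, c, d)
        obs = np.array([[a, b], [c, d]], dtype=float)
        total = obs.sum()
        expected_chi2 = 0.0
        for i in range(2):
            for j in range(2):
                e = obs[i].sum() * obs[:, j].sum() / total
                expected_chi2 += (obs[i, j] - e) ** 2 / e
        assert chi2 == pytest.approx(expected_chi2, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 10)

    def test_percent_helper(self):
        assert round(percent(75, 167), 2) == 44.91


class TestTwoSampleT:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = two_sample_t(x, x)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_large_shift_tiny_p(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        _, p = two_sample_t(a, b)
        assert p < 1e-10

    def test_matches_hand_computed_welch(self):
        a = np.array([4.1, 5.0, 6.2, 5.5, 4.8])
        b = np.array([3.0, 3.4, 2.9, 3.8, 3.1])
        t, p = two_sample_t(a, b)
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), df)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)

    def test_zero_variance_equal_means_degenerate(self):
        with pytest.warns(UserWarning):
            t, p = two_sample_t(np.full(5, 2.0), np.full(7, 2.0))
        assert (t, p) == (0.0, 1.0)
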