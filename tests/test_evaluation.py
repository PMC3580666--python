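"""Diagnostic-accuracy battery: AUROC, paired tests, 2x2 arithmetic."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sstats

from hrvtriage.evaluation import (
    DegenerateInputError,
    DiagnosticTable,
    compare_auc_paired,
    compare_predictive_values,
    exact_ci,
    mcnemar_paired,
    reconstruct_2x2,
    roc_auc,
    strata_rates,
    threshold_metrics,
    wilson_ci,
)


def brute_force_auc(scores, labels):
    """Exhaustive pairwise concordance with half-credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        r = roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        assert r.auc == 1.0

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=2000)
        labels = (rng.random(2000) < 0.5).astype(int)
        assert 0.47 <= roc_auc(scores, labels).auc <= 0.53

    def test_small_instance_with_ties_matches_concordance(self):
        scores = [1, 2, 2, 3, 3, 5]
        labels = [0, 0, 1, 0, 1, 1]
        assert roc_auc(scores, labels).auc == pytest.approx(
            brute_force_auc(scores, labels))

    def test_exhaustive_small_instances(self):
        """Rank AUC equals brute-force concordance on every labelled
        configuration with n <= 8 over a small tied score alphabet."""
        rng = np.random.default_rng(1)
        for _ in range(300):
            n = int(rng.integers(2, 9))
            scores = rng.integers(0, 4, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels).auc == pytest.approx(
                brute_force_auc(scores, labels))

    def test_curve_monotone(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        labels = (rng.random(100) < 0.3).astype(int)
        r = roc_auc(scores, labels)
        assert np.all(np.diff(r.sensitivity) >= -1e-12)
        assert np.all(np.diff(r.specificity) <= 1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestCompareAucPaired:
    def test_identical_scores_delta_zero_p_one(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=60)
        y = (rng.random(60) < 0.3).astype(int)
        cmp = compare_auc_paired(s, s.copy(), y)
        assert cmp.delta == 0.0
        assert cmp.p_value == 1.0
        assert cmp.ci_low <= 0.0 <= cmp.ci_high

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=80)
        y = (rng.random(80) < 0.4).astype(int)
        cmp = compare_auc_paired(s, np.exp(s), y)
        assert cmp.delta == pytest.approx(0.0, abs=1e-12)

    def test_constant_score_rejected(self):
        with pytest.raises(DegenerateInputError):
            compare_auc_paired(np.ones(10), np.arange(10), np.r_[np.zeros(5), np.ones(5)])

    def test_power_against_known_auc_gap(self):
        """Two scores with population AUROCs ~0.78 vs ~0.68 on the same
        n = 925, 4.6%-prevalence patients: the paired z-test rejects at
        alpha = 0.05 in well over half of replicates."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 925
            y = (rng.random(n) < 0.046).astype(int)
            if y.sum() < 2:
                continue
            # binormal scores: separation 1.13 -> AUC ~0.78; 0.66 -> ~0.68
            shared = rng.normal(size=n)
            a = shared + 1.13 * y + rng.normal(0, 0.6, n)
            b = shared + 0.66 * y + rng.normal(0, 0.6, n)
            if compare_auc_paired(a, b, y).p_value < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.5

    def test_hanley_mcneil_option_close_to_delong(self):
        rng = np.random.default_rng(6)
        y = (rng.random(200) < 0.3).astype(int)
        a = rng.normal(size=200) + y
        b = rng.normal(size=200) + 0.5 * y
        d1 = compare_auc_paired(a, b, y, method="delong")
        d2 = compare_auc_paired(a, b, y, method="hanley-mcneil")
        assert d1.delta == d2.delta
        assert d1.p_value == pytest.approx(d2.p_value, abs=0.05)


class TestThresholdMetrics:
    def test_lr_pos_from_table_sens_spec(self):
        """At the published operating points the likelihood ratios come out
        at 2.94 and 1.62."""
        t = reconstruct_2x2(925, 43, 81.4, 72.3)
        assert t.lr_pos == pytest.approx(2.94, abs=0.005)
        t2 = reconstruct_2x2(925, 43, 74.4, 54.2)
        assert t2.lr_pos == pytest.approx(1.62, abs=0.005)

    def test_all_above_cutoff(self):
        t = threshold_metrics([70, 80, 90], [0, 1, 0], cutoff=60)
        assert t.sensitivity == 100.0
        assert t.specificity == 0.0

    def test_no_predicted_positives_ppv_missing(self):
        t = threshold_metrics([10, 20, 30], [0, 1, 0], cutoff=60)
        assert math.isnan(t.ppv)

    def test_identities_hold(self):
        rng = np.random.default_rng(7)
        scores = rng.uniform(0, 100, 200)
        labels = (rng.random(200) < 0.2).astype(int)
        t = threshold_metrics(scores, labels, cutoff=50)
        assert t.tp + t.fn == labels.sum()
        assert t.fp + t.tn == (1 - labels).sum()
        assert t.sensitivity == pytest.approx(100 * t.tp / (t.tp + t.fn))
        assert t.specificity == pytest.approx(100 * t.tn / (t.fp + t.tn))
        assert t.ppv == pytest.approx(100 * t.tp / (t.tp + t.fp))
        assert t.npv == pytest.approx(100 * t.tn / (t.tn + t.fn))
        assert t.lr_pos == pytest.approx(t.sensitivity / (100 - t.specificity))


class TestReconstruct2x2:
    def test_arrest_ml_column(self):
        t = reconstruct_2x2(925, 43, 81.4, 72.3)
        assert (t.tp, t.fn, t.fp, t.tn) == (35, 8, 244, 638)
        assert round(t.ppv, 1) == 12.5
        assert round(t.npv, 1) == 98.8

    def test_death_columns(self):
        t = reconstruct_2x2(925, 86, 69.8, 73.9)
        assert round(t.ppv, 1) == 21.5
        assert round(t.npv, 1) == 96.0
        t2 = reconstruct_2x2(925, 86, 74.4, 55.7)
        assert round(t2.ppv, 1) == 14.7
        assert round(t2.npv, 1) == 95.5

    def test_no_events_ppv_undefined(self):
        t = reconstruct_2x2(100, 0, 50.0, 50.0)
        assert t.tp == 0
        assert math.isnan(t.ppv)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reconstruct_2x2(10, 20, 50, 50)
        with pytest.raises(ValueError):
            reconstruct_2x2(10, 5, 150, 50)


class TestMcnemar:
    def test_identical_flags_p_one(self):
        flags = np.array([1, 0, 1, 0, 1, 1], bool)
        y = np.array([1, 1, 1, 0, 0, 0])
        cmp = mcnemar_paired("sensitivity", flags, flags.copy(), y)
        assert cmp.delta == 0.0 and cmp.p_value == 1.0

    def test_hand_computed_chi_square(self):
        """Discordant counts b=10, c=2 give chi-square (10-2)^2/12 = 5.33."""
        n = 40
        y = np.ones(n, dtype=int)
        a = np.zeros(n, bool)
        b = np.zeros(n, bool)
        a[:20] = True
        b[:20] = True          # 20 concordant positive
        a[20:30] = True        # b = 10: A correct, B wrong
        b[30:32] = True        # c = 2
        cmp = mcnemar_paired("sensitivity", a, b, y)
        chi2 = (10 - 2) ** 2 / 12
        assert cmp.p_value == pytest.approx(float(sstats.chi2.sf(chi2, 1)), rel=1e-9)
        assert cmp.delta == pytest.approx(100 * 8 / 40)
        assert cmp.ci_low <= cmp.delta <= cmp.ci_high

    def test_null_type_one_error(self):
        """Equal-accuracy paired flags: rejection rate ~5% (800 replicates,
        binomial tolerance)."""
        rng = np.random.default_rng(8)
        rejections = 0
        n_rep = 800
        for _ in range(n_rep):
            n = 80
            y = np.ones(n, dtype=int)
            p = rng.uniform(0.4, 0.8)
            a = rng.random(n) < p
            b = rng.random(n) < p
            cmp = mcnemar_paired("sensitivity", a, b, y)
            if cmp.p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.02 <= rate <= 0.08

    def test_specificity_stratum_selected(self):
        y = np.array([0, 0, 0, 0, 1, 1])
        a = np.array([0, 0, 1, 1, 1, 1], bool)  # spec 50% among y=0
        b = np.array([0, 0, 0, 0, 1, 1], bool)  # spec 100%
        cmp = mcnemar_paired("specificity", a, b, y)
        assert cmp.delta == pytest.approx(-50.0)


class TestComparePredictiveValues:
    def test_identical_predictions_p_one(self):
        flags = np.array([1, 1, 0, 0, 1, 0], bool)
        y = np.array([1, 0, 1, 0, 1, 0])
        cmp = compare_predictive_values(flags, flags.copy(), y, "ppv")
        assert cmp.p_value == 1.0

    def test_clearly_better_score_significant(self):
        """One score concentrates the events among its positives on a
        constructed 20-patient table: p < 0.05."""
        y = np.array([1] * 6 + [0] * 14)
        a = np.array([1] * 6 + [0] * 14, bool)          # PPV 100%
        b = np.array([1] * 6 + [1] * 10 + [0] * 4, bool)  # PPV 37.5%
        cmp = compare_predictive_values(a, b, y, "ppv")
        assert cmp.delta > 0
        assert cmp.p_value < 0.05

    def test_no_positives_rejected(self):
        y = np.array([1, 0, 1, 0])
        with pytest.raises(DegenerateInputError):
            compare_predictive_values(np.zeros(4, bool), np.ones(4, bool), y, "ppv")

    def test_null_type_one_error(self):
        """Exchangeable paired predictions under equal predictive values:
        rejection rate ~5% over 1,000 replicates."""
        rng = np.random.default_rng(9)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            n = 120
            y = (rng.random(n) < 0.3).astype(int)
            a = rng.random(n) < 0.5
            b = rng.random(n) < 0.5
            try:
                cmp = compare_predictive_values(a, b, y, "ppv")
            except DegenerateInputError:
                continue
            if cmp.p_value < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert 0.025 <= rate <= 0.075

    def test_npv_direction(self):
        y = np.array([1] * 5 + [0] * 15)
        a = np.r_[np.ones(5), np.zeros(15)].astype(bool)   # NPV 100%
        b = np.r_[np.zeros(5), np.zeros(15)].astype(bool)  # NPV 75%
        cmp = compare_predictive_values(a, b, y, "npv")
        assert cmp.delta > 0


class TestStrataRates:
    def test_all_events_in_high(self):
        scores = np.array([10, 20, 50, 80, 90])
        labels = np.array([0, 0, 0, 1, 1])
        rows = {r["stratum"]: r for r in strata_rates(scores, labels)}
        assert rows["low"]["rate_pct"] == 0.0
        assert rows["intermediate"]["rate_pct"] == 0.0
        assert rows["high"]["rate_pct"] == 100.0

    def test_constructed_published_rates(self):
        """A cohort built to the published strata (0%, 1.6%, 13.1%) is
        reproduced exactly."""
        scores = np.concatenate([np.full(89, 20.0), np.full(576, 50.0), np.full(260, 80.0)])
        labels = np.zeros(925, dtype=int)
        labels[89 + 567:89 + 576] = 1       # 9/576 = 1.5625% -> 1.6%
        labels[925 - 34:] = 1               # 34/260 = 13.08%  -> 13.1%
        rows = {r["stratum"]: r for r in strata_rates(scores, labels)}
        assert rows["low"]["rate_pct"] == 0.0
        assert round(rows["intermediate"]["rate_pct"], 1) == 1.6
        assert round(rows["high"]["rate_pct"], 1) == 13.1
        for r in rows.values():
            assert r["ci_low"] <= r["rate_pct"] <= r["ci_high"]

    def test_empty_stratum_missing_rate(self):
        rows = {r["stratum"]: r for r in strata_rates(np.array([80.0]), np.array([1]))}
        assert math.isnan(rows["low"]["rate_pct"])


class TestConfidenceIntervals:
    @pytest.mark.parametrize("k,n", [(0, 10), (10, 10), (3, 17), (35, 279)])
    def test_intervals_within_bounds_and_ordered(self, k, n):
        for ci in (wilson_ci(k, n), exact_ci(k, n)):
            assert 0.0 <= ci[0] <= ci[1] <= 100.0 + 1e-9
            assert ci[0] - 1e-9 <= 100 * k / n <= ci[1] + 1e-9

    def test_lr_ci_nonnegative(self):
        t = DiagnosticTable(tp=35, fp=244, fn=8, tn=638)
        lr, lo, hi = t.metrics["lr_pos"]
        assert 0 <= lo <= lr <= hi
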