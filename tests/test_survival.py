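"""Correlation, Kaplan–Meier, log-rank, Cox, ROC/Youden and staging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bmquant import (binary_outcome_at_horizon, cox_fit, dichotomize_at_median,
                     iss_stage, km_estimate, log_rank_test,
                     median_followup_inverse_km, r_iss_stage, roc_at_horizon,
                     roc_youden, spearman_corr)


class TestSpearman:
    def test_perfect_monotone_pairs(self):
        x = np.arange(1.0, 11.0)
        assert spearman_corr(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman_corr(x, -x)[0] == pytest.approx(-1.0)

    def test_rank_formula_oracle(self):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) with d = (0, 1, -1, 0) -> 0.8
        rho, _ = spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert rho == pytest.approx(0.8)

    def test_constant_vector_flagged_undefined(self):
        with pytest.warns(UserWarning, match="constant"):
            rho, p = spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_invariant_under_strictly_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        rho1, _ = spearman_corr(x, y)
        rho2, _ = spearman_corr(np.exp(x), y ** 3)
        assert rho1 == pytest.approx(rho2)


class TestKaplanMeier:
    def test_all_events_at_same_time(self):
        km = km_estimate([5.0] * 10, [1] * 10)
        assert km.median_months == 5.0
        assert km.n_events == 10

    def test_all_censored_median_not_reached(self):
        km = km_estimate([10.0] * 8, [0] * 8)
        assert not km.median_reached
        assert km.median_months == np.inf

    def test_curve_nonincreasing_from_one(self):
        rng = np.random.default_rng(1)
        km = km_estimate(rng.exponential(10, 50), rng.random(50) < 0.7)
        assert km.survival[0] == 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        times = np.array([1.0, 2.0, 2.0, 3.0, 5.0])
        km = km_estimate(times, np.ones(5))
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx((times > t).mean())

    def test_exponential_median_closed_form(self):
        rng = np.random.default_rng(2)
        rate = np.log(2) / 12.0
        km = km_estimate(rng.exponential(1 / rate, 2000), np.ones(2000))
        assert km.median_months == pytest.approx(12.0, rel=0.05)


class TestInverseKM:
    def test_all_censored_at_fixed_time(self):
        assert median_followup_inverse_km([110.0] * 6, [0] * 6) == 110.0

    def test_all_events_flagged_not_estimable(self):
        with pytest.warns(UserWarning, match="not estimable"):
            assert median_followup_inverse_km([5.0, 8.0, 2.0], [1, 1, 1]) == np.inf

    def test_mixed_records_match_reverse_product_limit_oracle(self):
        time = np.array([3.0, 5.0, 7.0, 9.0, 11.0, 13.0])
        event = np.array([1, 0, 1, 0, 0, 0])
        # reverse roles: "events" at 5, 9, 11, 13; brute-force product limit
        flipped = 1 - event
        at_risk = len(time)
        surv = 1.0
        median = None
        for t in np.sort(time):
            i = np.where(time == t)[0][0]
            if flipped[i]:
                surv *= (at_risk - 1) / at_risk
            at_risk -= 1
            if median is None and surv <= 0.5:
                median = t
        assert median_followup_inverse_km(time, event) == pytest.approx(median)


class TestLogRank:
    def test_identical_groups_give_null_result(self):
        time = np.array([2.0, 4.0, 6.0, 8.0] * 2)
        event = np.ones(8)
        group = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        chi2, p = log_rank_test(time, event, group)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            log_rank_test([1.0, 2.0], [1, 1], [0, 0])

    def test_toy_table_matches_observed_minus_expected_oracle(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.ones(6, dtype=int)
        group = np.array([0, 1, 0, 1, 0, 1])
        # direct O-E computation over distinct event times
        o_minus_e, var = 0.0, 0.0
        for t in np.unique(time):
            at_risk = time >= t
            d = (event == 1) & (time == t)
            n, n1 = at_risk.sum(), (at_risk & (group == 0)).sum()
            d_tot, d1 = d.sum(), (d & (group == 0)).sum()
            e1 = d_tot * n1 / n
            o_minus_e += d1 - e1
            if n > 1:
                var += d_tot * (n1 / n) * (1 - n1 / n) * (n - d_tot) / (n - 1)
        expected_chi2 = o_minus_e ** 2 / var
        chi2, _ = log_rank_test(time, event, group)
        assert chi2 == pytest.approx(expected_chi2, rel=1e-6)


class TestDichotomize:
    def test_high_group_is_strictly_above_median(self):
        assert list(dichotomize_at_median([1, 2, 3, 4])) == [0, 0, 1, 1]

    def test_ties_at_median_go_low(self):
        assert list(dichotomize_at_median([1, 2, 2, 3])) == [0, 0, 0, 1]

    def test_all_equal_warns_empty_high_group(self):
        with pytest.warns(UserWarning, match="empty high group"):
            labels = dichotomize_at_median([2.0, 2.0, 2.0])
        assert labels.sum() == 0


class TestCox:
    def test_null_covariate_ci_covers_one(self):
        rng = np.random.default_rng(3)
        n = 1000
        df = pd.DataFrame({
            "time_months": rng.exponential(20, n),
            "event": np.ones(n, dtype=int),
            "x": rng.normal(size=n),
        })
        fit = cox_fit(df, ["x"])
        assert fit.ci_lower["x"] < 1.0 < fit.ci_upper["x"]

    def test_two_group_rate_ratio_recovered(self):
        rng = np.random.default_rng(4)
        n = 2000
        group = np.repeat([0, 1], n // 2)
        rate = np.where(group == 1, 0.2, 0.1)  # true HR = 2
        df = pd.DataFrame({
            "time_months": rng.exponential(1 / rate),
            "event": np.ones(n, dtype=int),
            "group": group,
        })
        fit = cox_fit(df, ["group"])
        assert 1.8 <= fit.hazard_ratios["group"] <= 2.2
        assert fit.ci_lower["group"] < fit.hazard_ratios["group"] < fit.ci_upper["group"]

    def test_efron_and_breslow_agree_without_ties(self):
        rng = np.random.default_rng(5)
        n = 200
        df = pd.DataFrame({
            "time_months": rng.exponential(10, n),  # continuous: no ties
            "event": (rng.random(n) < 0.8).astype(int),
            "x": rng.normal(size=n),
        })
        efron = cox_fit(df, ["x"], ties="efron")
        breslow = cox_fit(df, ["x"], ties="breslow")
        assert efron.hazard_ratios["x"] == pytest.approx(breslow.hazard_ratios["x"],
                                                         rel=1e-4)

    def test_cross_check_against_independent_backend(self):
        # lifelines (implementation route) vs statsmodels PHReg with Efron ties
        from statsmodels.duration.hazard_regression import PHReg
        rng = np.random.default_rng(6)
        n = 300
        x = rng.normal(size=n)
        t = rng.exponential(np.exp(-0.5 * x) * 10)
        df = pd.DataFrame({"time_months": t, "event": np.ones(n, dtype=int), "x": x})
        fit = cox_fit(df, ["x"], ties="efron")
        res = PHReg(t, x.reshape(-1, 1), status=np.ones(n), ties="efron").fit(disp=False)
        assert fit.hazard_ratios["x"] == pytest.approx(float(np.exp(res.params[0])),
                                                       rel=1e-5)

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 1, 1],
                           "x": [2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            cox_fit(df, ["x"])

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time_months": [1.0, 2.0, 3.0], "event": [1, 0, 0],
                           "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="two events"):
            cox_fit(df, ["x"])


class TestHorizonOutcome:
    def test_classification_rules(self):
        time = np.array([10.0, 12.0, 30.0, 24.0, 25.0])
        event = np.array([1, 0, 0, 1, 1])
        labels, evaluable = binary_outcome_at_horizon(time, event, 24.0)
        assert labels[0] == 1            # event at 10 months: positive
        assert not evaluable[1]          # censored at 12 months: excluded
        assert labels[2] == 0            # censored at 30 months: negative
        assert labels[3] == 1            # event exactly at the horizon: positive
        assert labels[4] == 0            # event after the horizon: negative

    def test_nothing_evaluable_is_an_error(self):
        with pytest.raises(ValueError, match="evaluable"):
            binary_outcome_at_horizon([5.0, 6.0], [0, 0], 24.0)


class TestRocYouden:
    def test_perfect_separation(self):
        r = roc_youden([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3 < r.cut_point <= 10

    def test_four_point_worked_set(self):
        r = roc_youden([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert 2.0 < r.cut_point < 3.0  # cut falls between the classes

    def test_exhaustive_threshold_oracle_on_small_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(4, 9))
            marker = np.round(rng.normal(size=n), 2)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            r = roc_youden(marker, labels)
            pos, neg = marker[labels == 1], marker[labels == 0]
            # oracle: scan every real cut (all pairwise midpoints and beyond)
            candidates = np.concatenate([[marker.min() - 1], marker,
                                         (np.sort(marker)[:-1] + np.sort(marker)[1:]) / 2,
                                         [marker.max() + 1]])
            best_j = max(float((pos >= c).mean() + (neg < c).mean() - 1)
                         for c in candidates)
            assert r.sensitivity + r.specificity - 1 == pytest.approx(best_j, abs=1e-12)
            # AUC equals the Mann-Whitney statistic
            u = sum(1.0 if p > q else 0.5 if p == q else 0.0
                    for p in pos for q in neg)
            assert r.auc == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_independent_marker_auc_near_half(self):
        rng = np.random.default_rng(8)
        n = 2000
        r = roc_youden(rng.normal(size=n), rng.integers(0, 2, n))
        assert abs(r.auc - 0.5) < 0.03

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        marker = rng.normal(size=100)
        labels = (marker + rng.normal(size=100) > 0).astype(int)
        assert roc_youden(marker, labels).auc == pytest.approx(
            roc_youden(np.exp(marker), labels).auc)

    def test_delong_ci_matches_r_proc_oracle(self):
        # frozen from pROC 1.19 ci.auc(..., method="delong") on this fixture
        marker = [0.2, 0.9, 0.4, 0.7, 0.1, 0.3, 0.55, 0.35, 0.6, 0.25]
        labels = [0, 1, 0, 1, 0, 1, 1, 0, 0, 1]
        r = roc_youden(marker, labels)
        assert r.auc == pytest.approx(0.72, abs=1e-10)
        assert r.auc_ci[0] == pytest.approx(0.3650354253, abs=1e-9)
        assert r.auc_ci[1] == pytest.approx(1.0, abs=1e-9)

    def test_one_class_absent_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            roc_youden([1.0, 2.0], [1, 1])

    def test_ipcw_mode_matches_binary_without_censoring(self):
        rng = np.random.default_rng(10)
        n = 400
        marker = rng.normal(size=n)
        time = rng.exponential(30 * np.exp(-0.5 * marker))
        df = pd.DataFrame({"time_months": np.maximum(time, 1e-6),
                           "event": np.ones(n, dtype=int), "mtv_ml": marker})
        binary = roc_at_horizon(df, "mtv_ml", 24.0, method="binary")
        ipcw = roc_at_horizon(df, "mtv_ml", 24.0, method="ipcw")
        assert ipcw.auc == pytest.approx(binary.auc, abs=1e-9)


class TestStaging:
    @pytest.mark.parametrize("b2m, albumin, expected", [
        (3.0, 4.0, 1),   # low b2m, preserved albumin
        (3.0, 3.0, 2),   # low b2m but low albumin
        (4.0, 4.0, 2),   # intermediate b2m
        (5.5, 4.0, 2),   # boundary stays II
        (6.0, 4.0, 3),   # b2m above 5.5
    ])
    def test_iss_rules(self, b2m, albumin, expected):
        assert iss_stage(b2m, albumin) == expected

    def test_r_iss_examples(self):
        assert r_iss_stage(iss_stage(3.0, 4.0), False, False) == 1
        assert r_iss_stage(iss_stage(6.0, 4.0), False, True) == 3
        assert r_iss_stage(iss_stage(3.0, 3.0), False, False) == 2

    def test_r_iss_exhaustive_truth_table(self):
        for iss in (1, 2, 3):
            for hr in (False, True):
                for ldh in (False, True):
                    stage = r_iss_stage(iss, hr, ldh)
                    if iss == 1 and not hr and not ldh:
                        assert stage == 1
                    elif iss == 3 and (hr or ldh):
                        assert stage == 3
                    else:
                        assert stage == 2
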