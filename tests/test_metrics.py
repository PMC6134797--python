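"""Validation metrics: concordance, Brier, calibration, risk groups."""

import numpy as np
import pandas as pd
import pytest

from priolasso.errors import DataValidationError, DegenerateOutcomeError
from priolasso.metrics import (
    HIGH,
    INTERMEDIATE,
    LOW,
    binary_metrics_at,
    brier_curve,
    calibration_slope,
    group_hazard_ratios,
    integrated_brier,
    logrank_cutpoints,
    multigroup_logrank_chi2,
    optimism,
    uno_c,
)

from conftest import simple_survival


def brute_force_uno(scores, time, status, tau):
    """Independent pair-enumeration oracle with an explicit censoring KM."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(time, 1 - np.asarray(status))
    G_minus = lambda t: float(
        km.survival_function_at_times(t - 1e-9).iloc[0]
    )
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        if status[i] != 1 or time[i] >= tau:
            continue
        w = 1.0 / G_minus(time[i]) ** 2
        for j in range(n):
            if time[i] < time[j]:
                den += w
                if scores[i] > scores[j]:
                    num += w
                elif scores[i] == scores[j]:
                    num += 0.5 * w
    return num / den


class TestUnoC:
    def test_perfect_ranking_no_censoring(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        scores = -time  # higher score = shorter survival
        assert uno_c(scores, time, np.ones(5), tau=4.5) == 1.0

    def test_constant_score_is_half(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        assert uno_c(np.zeros(4), time, np.ones(4), tau=3.5) == 0.5

    def test_six_subject_fixture_matches_enumeration(self):
        time = np.array([1.0, 2.0, 2.5, 3.0, 4.0, 6.0])
        status = np.array([1, 1, 0, 1, 0, 1])
        scores = np.array([2.0, 1.0, 0.5, 1.5, -0.5, 0.0])
        tau = 5.0
        expected = brute_force_uno(scores, time, status, tau)
        assert np.isclose(uno_c(scores, time, status, tau=tau), expected, atol=1e-10)

    def test_flip_symmetry_without_censoring(self):
        rng = np.random.default_rng(4)
        time = rng.exponential(size=15) + 0.1
        scores = rng.normal(size=15)
        c1 = uno_c(scores, time, np.ones(15), tau=np.quantile(time, 0.9))
        c2 = uno_c(-scores, time, np.ones(15), tau=np.quantile(time, 0.9))
        assert np.isclose(c1 + c2, 1.0, atol=1e-12)

    def test_matches_sksurv(self):
        from sksurv.metrics import concordance_index_ipcw

        sc, t, s = None, None, None
        _, t, s = simple_survival(n=80, seed=6, beta=[1, 0, 0, 0])
        sc = np.random.default_rng(7).normal(size=80) + 0.001 * t
        tau = float(np.quantile(t, 0.8))
        y = np.array(
            [(bool(e), ti) for e, ti in zip(s, t)],
            dtype=[("e", bool), ("t", float)],
        )
        expected = concordance_index_ipcw(y, y, sc, tau=tau)[0]
        assert np.isclose(uno_c(sc, t, s, tau=tau), expected, atol=1e-12)

    def test_no_comparable_pairs(self):
        with pytest.raises(DegenerateOutcomeError):
            uno_c([1.0, 2.0], [5.0, 6.0], [0, 0], tau=4.0)


class TestBrier:
    def test_oracle_predictions_score_zero(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        ts = np.array([0.5, 1.5, 2.5, 3.5])
        # S_i(t) jumps 1 -> 0 exactly at the subject's event time
        S = (time[:, None] > ts[None, :]).astype(float)
        bs = brier_curve(S, time, np.ones(4), ts)
        np.testing.assert_allclose(bs, np.zeros(4), atol=1e-15)

    def test_constant_one_prediction_gives_ecdf(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        ts = np.array([0.5, 1.5, 2.5, 3.5])
        S = np.ones((4, 4))
        bs = brier_curve(S, time, np.ones(4), ts)
        np.testing.assert_allclose(bs, [0.0, 0.25, 0.5, 0.75])

    def test_censored_fixture_matches_hand_ipcw_sums(self):
        """5 subjects with censoring: term-by-term IPCW oracle."""
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        status = np.array([1, 0, 1, 0, 1])
        rng = np.random.default_rng(8)
        S = np.clip(rng.uniform(0.2, 1.0, size=(5, 3)), 0, 1)
        S.sort(axis=1)
        S = S[:, ::-1].copy()
        ts = np.array([1.5, 2.5, 3.5])
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(time, 1 - status)
        G = lambda x: float(km.survival_function_at_times(x).iloc[0])
        G_minus = lambda x: float(km.survival_function_at_times(x - 1e-9).iloc[0])
        expected = []
        for k, t in enumerate(ts):
            total = 0.0
            for i in range(5):
                if time[i] <= t and status[i] == 1:
                    total += S[i, k] ** 2 / G_minus(time[i])
                elif time[i] > t:
                    total += (1 - S[i, k]) ** 2 / G(t)
            expected.append(total / 5)
        np.testing.assert_allclose(
            brier_curve(S, time, status, ts), expected, atol=1e-10
        )

    def test_sample_order_invariance(self):
        _, t, s = simple_survival(n=25, seed=9)
        rng = np.random.default_rng(10)
        S = np.sort(rng.uniform(size=(25, 4)), axis=1)[:, ::-1].copy()
        ts = np.quantile(t, [0.2, 0.4, 0.6, 0.8])
        perm = rng.permutation(25)
        np.testing.assert_allclose(
            brier_curve(S, t, s, ts), brier_curve(S[perm], t[perm], s[perm], ts)
        )

    def test_integrated_brier_trapezoid(self):
        ts = np.array([0.0, 1.0, 2.0])
        bs = np.array([0.0, 0.2, 0.4])
        # trapezoid of a linear curve: mean value 0.2 over [0, 2]
        assert np.isclose(integrated_brier(ts, bs, 2.0), 0.2)
        assert integrated_brier(ts, bs, 2.0) >= 0
        with pytest.raises(DataValidationError):
            integrated_brier(ts, bs, 5.0)


class TestCalibration:
    def test_own_linear_predictor_has_slope_one(self):
        from lifelines import CoxPHFitter

        X, t, s = simple_survival(n=150, seed=11, beta=[1.0, -0.5, 0.3, 0.0])
        df = pd.DataFrame(X, columns=list("abcd"))
        df["time"], df["status"] = t, s
        cph = CoxPHFitter().fit(
            df, "time", "status", fit_options={"precision": 1e-10}
        )
        lp = X @ cph.params_.to_numpy()
        assert abs(calibration_slope(lp, t, s) - 1.0) < 1e-6

    def test_scale_equivariance(self):
        _, t, s = simple_survival(n=100, seed=12, beta=[1, 0, 0, 0])
        sc = np.random.default_rng(13).normal(size=100) + 0.2 * t
        s1 = calibration_slope(sc, t, s)
        s2 = calibration_slope(2.0 * sc, t, s)
        assert np.isclose(s2, s1 / 2.0, rtol=1e-6)

    def test_null_slope_near_zero(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(4000 + seed)
            sc = rng.normal(size=500)
            T = rng.exponential(size=500)
            C = rng.exponential(scale=2.0, size=500)
            t, s = np.minimum(T, C), (T <= C).astype(int)
            ok += abs(calibration_slope(sc, t, s)) < 0.15
        assert ok / 20 >= 0.9

    def test_constant_score_rejected(self):
        with pytest.raises(DataValidationError):
            calibration_slope(np.ones(10), np.arange(1.0, 11.0), np.ones(10))

    def test_optimism_is_plain_difference(self):
        assert optimism(1.0, 0.6) == pytest.approx(0.4)


class TestLogrankCutpoints:
    def test_matches_lifelines_statistic(self):
        from lifelines.statistics import multivariate_logrank_test

        _, t, s = simple_survival(n=60, seed=14, beta=[1, 0, 0, 0])
        labels = np.random.default_rng(15).integers(0, 3, size=60)
        expected = multivariate_logrank_test(t, labels, s).test_statistic
        assert np.isclose(multigroup_logrank_chi2(labels, t, s), expected, rtol=1e-9)

    def test_three_cluster_construction(self):
        """Clusters with hazard rates (0.1, 0.5, 2.0): the recovered
        cutpoints separate the score clusters almost perfectly."""
        rng = np.random.default_rng(16)
        n_per = 50
        scores = np.concatenate(
            [rng.uniform(0, 1, n_per), rng.uniform(2, 3, n_per), rng.uniform(4, 5, n_per)]
        )
        true = np.repeat([LOW, INTERMEDIATE, HIGH], n_per)
        rates = np.repeat([0.1, 0.5, 2.0], n_per)
        T = rng.exponential(1 / rates)
        C = rng.uniform(0, 15, size=3 * n_per)
        t, s = np.minimum(T, C), (T <= C).astype(int)
        groups = logrank_cutpoints(scores, t, s)
        c1, c2 = groups.cutpoints
        assert 0.0 < c1 < 3.0 and 2.0 < c2 < 5.0  # one cutpoint per gap region
        # maximal selection may shift by a few boundary samples, no more
        assert np.mean(groups.assign(scores) == true) >= 0.9

    def test_matches_exhaustive_search_on_30_samples(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(17)
        n = 30
        scores = rng.normal(size=n)
        T = rng.exponential(np.exp(-scores))
        C = rng.exponential(scale=2.0, size=n)
        t, s = np.minimum(T, C) + 1e-9, (T <= C).astype(int)
        groups = logrank_cutpoints(scores, t, s, min_group_frac=0.1)
        # brute force with an independent statistic implementation
        order = np.sort(np.unique(scores))
        mids = (order[:-1] + order[1:]) / 2
        min_size = 3
        best_stat = -1.0
        for c1 in mids:
            for c2 in mids:
                if c2 <= c1:
                    continue
                lab = np.where(scores < c1, 0, np.where(scores < c2, 1, 2))
                sizes = np.bincount(lab, minlength=3)
                if sizes.min() < min_size:
                    continue
                stat = multivariate_logrank_test(t, lab, s).test_statistic
                best_stat = max(best_stat, stat)
        assert np.isclose(groups.chi2, best_stat, rtol=1e-8)

    def test_monotone_transform_invariance(self):
        _, t, s = simple_survival(n=50, seed=18, beta=[1, 0, 0, 0])
        sc = np.random.default_rng(19).normal(size=50)
        g1 = logrank_cutpoints(sc, t, s)
        g2 = logrank_cutpoints(np.exp(sc), t, s)
        np.testing.assert_array_equal(g1.labels, g2.labels)
        assert np.isclose(g1.chi2, g2.chi2)

    def test_null_score_returns_valid_groups(self):
        rng = np.random.default_rng(20)
        sc = rng.normal(size=60)
        t = rng.exponential(size=60) + 0.01
        groups = logrank_cutpoints(sc, t, np.ones(60))
        sizes = groups.sizes()
        assert all(v >= 6 for v in sizes.values())


class TestGroupHazardRatios:
    @staticmethod
    def _tertile_labels(sc):
        q1, q2 = np.quantile(sc, [1 / 3, 2 / 3])
        return np.where(sc < q1, LOW, np.where(sc < q2, INTERMEDIATE, HIGH))

    def test_null_groups_have_hr_near_one(self):
        """Outcome-independent groups, n=600: HRs inside [0.7, 1.4]."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(5000 + seed)
            sc = rng.normal(size=600)
            T = rng.exponential(size=600)
            C = rng.exponential(scale=2.0, size=600)
            t, s = np.minimum(T, C), (T <= C).astype(int)
            hr = group_hazard_ratios(self._tertile_labels(sc), t, s)
            ok += (0.7 <= hr["hr_low"] <= 1.4) and (0.7 <= hr["hr_high"] <= 1.4)
        assert ok / 20 >= 0.9

    def test_graded_hazards_detected(self):
        """Rates (0.1, 0.5, 2.0) at n=300: HR_low < 1 < HR_high, LR p < 1e-3."""
        rng = np.random.default_rng(21)
        n_per = 100
        labels = np.repeat([LOW, INTERMEDIATE, HIGH], n_per)
        rates = np.repeat([0.1, 0.5, 2.0], n_per)
        T = rng.exponential(1 / rates)
        C = rng.uniform(0, 20, size=3 * n_per)
        t, s = np.minimum(T, C), (T <= C).astype(int)
        hr = group_hazard_ratios(labels, t, s)
        assert hr["hr_low"] < 1 < hr["hr_high"]
        assert hr["lr_pvalue"] < 1e-3
        assert hr["hr_low_ci"][0] <= hr["hr_low"] <= hr["hr_low_ci"][1]
        assert hr["hr_high_ci"][0] <= hr["hr_high"] <= hr["hr_high_ci"][1]

    def test_group_without_events_rejected(self):
        labels = np.repeat([LOW, INTERMEDIATE, HIGH], 5)
        t = np.arange(1.0, 16.0)
        s = np.array([0] * 5 + [1] * 10)  # low group: no events
        with pytest.raises(DegenerateOutcomeError):
            group_hazard_ratios(labels, t, s)


class TestBinaryMetricsAtHorizon:
    def test_perfect_split(self):
        time = np.array([0.5, 1.0, 1.5, 4.0, 5.0, 6.0])
        status = np.ones(6)
        score = np.array([3.0, 2.5, 2.0, -1.0, -2.0, -3.0])
        m = binary_metrics_at(score, time, status, horizon=2.0)
        assert m["tpr"] == m["tnr"] == m["auc"] == 1.0

    def test_eight_subject_hand_fixture(self):
        time = np.array([0.5, 1.0, 1.2, 1.8, 3.0, 4.0, 0.7, 5.0])
        status = np.array([1, 1, 0, 1, 0, 1, 1, 0])
        score = np.array([2.0, 1.0, 0.0, -1.0, 0.5, -0.5, 1.5, -2.0])
        # cases: events at t <= 2 -> subjects 0, 1, 3, 6 (subject 2 censored early, excluded)
        # controls: time > 2 -> subjects 4, 5, 7
        # included scores: 2.0 1.0 -1.0 0.5 -0.5 1.5 -2.0 -> median 0.5
        # above 0.5: subjects 0, 1, 6 -> TPR 3/4; controls <= 0.5: all 3 -> TNR 1
        m = binary_metrics_at(score, time, status, horizon=2.0)
        assert m["n_cases"] == 4 and m["n_controls"] == 3
        assert m["cutoff"] == 0.5
        assert m["tpr"] == pytest.approx(3 / 4)
        assert m["tnr"] == pytest.approx(1.0)
        # concordant case/control pairs: case -1.0 vs controls 0.5,-0.5 discordant;
        # 10 of 12 pairs concordant -> AUC 10/12
        assert m["auc"] == pytest.approx(10 / 12)

    def test_null_score_auc_near_half(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(6000 + seed)
            sc = rng.normal(size=600)
            T = rng.exponential(size=600)
            t, s = T, np.ones(600)
            m = binary_metrics_at(sc, t, s, horizon=float(np.median(T)))
            ok += abs(m["auc"] - 0.5) < 0.05
        assert ok / 20 >= 0.9

    def test_no_cases_rejected(self):
        with pytest.raises(DegenerateOutcomeError):
            binary_metrics_at([1.0, 2.0], [5.0, 6.0], [1, 1], horizon=1.0)
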