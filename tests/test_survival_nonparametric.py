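"""KM, log-rank, concordance and RMST against hand computations and oracles."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index, restricted_mean_survival_time

from immunoscore.survival import (
    auto_tau,
    c_index,
    km_curve,
    logrank,
    rmst,
    rmst_difference,
)

from conftest import random_survival_data


class TestKaplanMeier:
    def test_all_censored_flat_curve(self):
        km = km_curve([5, 10, 15], [0, 0, 0])
        assert km.survival_at(0) == 1.0
        assert km.survival_at(100) == 1.0

    def test_hand_product_limit(self):
        km = km_curve([5, 10, 15], [1, 1, 1])
        assert km.survival_at(12) == pytest.approx(1 / 3)
        assert km.survival_at(4.9) == 1.0
        assert km.survival_at(15) == pytest.approx(0.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(21)
        for i in range(100):
            t, e = random_survival_data(rng, rng.integers(10, 150),
                                        round_times=i % 2 == 0)
            km = km_curve(t, e)
            kmf = KaplanMeierFitter().fit(t, e)
            for et in km.event_times:
                ours = km.survival_at(et)
                theirs = float(kmf.predict(et))
                assert abs(ours - theirs) < 1e-10

    def test_greenwood_ci_matches_lifelines(self):
        rng = np.random.default_rng(22)
        t, e = random_survival_data(rng, 200)
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ci = kmf.confidence_interval_survival_function_
        mid = np.median(km.event_times)
        s, lo, hi = km.rate_at(mid)
        row = ci.loc[ci.index <= mid].iloc[-1]
        assert lo == pytest.approx(row.iloc[0], abs=1e-8)
        assert hi == pytest.approx(row.iloc[1], abs=1e-8)

    def test_rate_bracket(self):
        rng = np.random.default_rng(23)
        t, e = random_survival_data(rng, 80)
        s, lo, hi = km_curve(t, e).rate_at(10.0)
        assert 0.0 <= lo <= s <= hi <= 1.0


def brute_force_logrank_two_groups(t1, e1, t2, e2):
    """Observed-minus-expected over explicit risk sets (oracle)."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2]).astype(bool)
    grp = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e, var = 0.0, 0.0
    for td in np.unique(times[events]):
        at_risk = times >= td
        n, n1 = at_risk.sum(), (at_risk & (grp == 0)).sum()
        d = (events & (times == td)).sum()
        d1 = (events & (times == td) & (grp == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        chi2, df, p = logrank(([1, 2, 3], [1, 0, 1]), ([1, 2, 3], [1, 0, 1]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert (df, p) == (1, pytest.approx(1.0))

    def test_six_patient_hand_example(self):
        t1, e1 = np.array([3.0, 6.0, 9.0]), np.array([1, 1, 0])
        t2, e2 = np.array([4.0, 8.0, 12.0]), np.array([1, 0, 1])
        chi2, df, _ = logrank((t1, e1), (t2, e2))
        assert df == 1
        assert chi2 == pytest.approx(brute_force_logrank_two_groups(t1, e1, t2, e2),
                                     abs=1e-12)

    def test_matches_lifelines_on_random_data(self):
        rng = np.random.default_rng(31)
        for i in range(100):
            k = int(rng.integers(2, 4))
            groups = [random_survival_data(rng, rng.integers(15, 80),
                                           round_times=i % 2 == 0)
                      for _ in range(k)]
            chi2, df, p = logrank(*groups)
            t = np.concatenate([g[0] for g in groups])
            e = np.concatenate([g[1] for g in groups])
            lab = np.concatenate([np.full(len(g[0]), j) for j, g in enumerate(groups)])
            res = multivariate_logrank_test(t, lab, e)
            assert abs(chi2 - res.test_statistic) < 1e-8
            assert df == k - 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(([1, 2], [1, 1]), ([], []))


class TestCIndex:
    def test_perfect_ranking(self):
        times = np.array([1.0, 2, 3, 4, 5])
        events = np.ones(5, bool)
        score = -times  # higher risk fails earlier
        c, lo, hi, n_pairs = c_index(score, times, events)
        assert c == 1.0 and n_pairs == 10

    def test_random_score_near_half(self):
        rng = np.random.default_rng(41)
        t, e = random_survival_data(rng, 2000)
        c, *_ = c_index(rng.normal(size=2000), t, e)
        assert abs(c - 0.5) < 0.02

    def test_three_patient_brute_force(self):
        # patient A: event at 2; B: censored at 4; C: event at 6
        times = np.array([2.0, 4.0, 6.0])
        events = np.array([True, False, True])
        score = np.array([3.0, 1.0, 2.0])
        # usable pairs: (A,B) concordant (3>1), (A,C) concordant (3>2);
        # (C,B) unusable: B censored before C's event... B's censoring at 4 < 6
        c, _, _, n_pairs = c_index(score, times, events)
        assert n_pairs == 2
        assert c == 1.0

    def test_matches_lifelines(self):
        # continuous times: no tied-time pairs, where conventions diverge
        rng = np.random.default_rng(42)
        for _ in range(20):
            t, e = random_survival_data(rng, 150)
            score = rng.normal(size=150) + 0.5 * (t < np.median(t))
            c, *_ = c_index(score, t, e)
            # lifelines concordance is for predicted survival time (higher = later)
            theirs = concordance_index(t, -score, e)
            assert c == pytest.approx(theirs, abs=1e-12)

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValueError):
            c_index([1.0, 2.0], [5.0, 5.0], [False, False])


class TestRMST:
    def test_no_events_equals_tau(self):
        r = rmst([100, 120, 130], [0, 0, 0], tau=90.0)
        assert r.rmst == pytest.approx(90.0)
        assert r.se == 0.0

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(51)
        lam, tau, n = 0.01, 120.0, 20000
        t = rng.exponential(1 / lam, size=n)
        c = np.full(n, 300.0)
        times, events = np.minimum(t, c), t <= c
        r = rmst(times, events, tau=tau)
        closed = (1 - np.exp(-lam * tau)) / lam  # 69.88 months
        assert abs(r.rmst - closed) / closed < 0.01

    def test_matches_lifelines(self):
        rng = np.random.default_rng(52)
        for _ in range(20):
            t, e = random_survival_data(rng, 200)
            tau = float(np.percentile(t, 80))
            r = rmst(t, e, tau=tau)
            kmf = KaplanMeierFitter().fit(t, e)
            theirs = restricted_mean_survival_time(kmf, t=tau)
            assert r.rmst == pytest.approx(float(theirs), abs=1e-8)

    def test_tau_beyond_followup_rejected(self):
        with pytest.raises(ValueError, match="auto_tau"):
            rmst([10, 20, 30], [1, 1, 0], tau=40.0)

    def test_auto_tau_rule(self):
        g = lambda m: (np.array([1.0, m]), np.array([1, 0]))
        assert auto_tau(g(250.0), g(180.0), g(240.0)) == 180.0
        assert auto_tau(g(75.0)) == 75.0

    def test_identical_groups_null_difference(self):
        rng = np.random.default_rng(53)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            a = random_survival_data(rng, 120)
            b = random_survival_data(rng, 120)
            diff, se, lo, hi, p, tau = rmst_difference(a, b)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.06
        assert lo <= diff <= hi

    def test_difference_sign(self):
        rng = np.random.default_rng(54)
        a = (rng.exponential(100, 400), np.ones(400, bool))
        b = (rng.exponential(30, 400), np.ones(400, bool))
        diff, *_ = rmst_difference(a, b, tau=50.0)
        assert diff > 0
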