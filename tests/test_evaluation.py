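import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itersurv.data_model import SurvivalDataset
from itersurv.evaluation import (
    censoring_km,
    cross_validate,
    iauc,
    km_estimate,
    rmse_uncensored,
    td_auc,
)


def brute_force_km(times, events, t):
    """Independent oracle: product over risk sets, straight from the
    product-limit definition."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    s = 1.0
    for u in sorted(set(times[events == 1])):
        if u > t:
            break
        n_at = np.sum(times >= u)
        d = np.sum((times == u) & (events == 1))
        s *= 1.0 - d / n_at
    return s


class TestKaplanMeier:
    def test_hand_example(self):
        curve = km_estimate([2, 4, 4, 6], [1, 1, 1, 0])
        assert curve.at(2) == pytest.approx(0.75)
        assert curve.at(4) == pytest.approx(0.25)
        assert curve.at(6) == pytest.approx(0.25)

    def test_no_censoring_matches_empirical_survival(self):
        times = np.arange(1.0, 11.0)
        curve = km_estimate(times, np.ones(10, int))
        for t in times:
            assert curve.at(t) == pytest.approx(np.mean(times > t))

    def test_all_censored_stays_at_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert curve.at(3.0) == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_matches_brute_force_on_all_small_patterns(self):
        # exhaustive over event patterns for n <= 6 with distinct times
        for n in range(1, 7):
            times = np.arange(1.0, n + 1.0)
            for pattern in itertools.product([0, 1], repeat=n):
                events = np.array(pattern)
                curve = km_estimate(times, events)
                for t in times:
                    assert curve.at(t) == pytest.approx(
                        brute_force_km(times, events, t), abs=1e-12
                    )

    def test_survival_non_increasing_with_greenwood_se(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(100, 80)
        e = rng.integers(0, 2, 80)
        curve = km_estimate(t, e)
        assert np.all(np.diff(curve.survival) <= 1e-12)
        assert np.all(curve.se >= 0)

    def test_agrees_with_lifelines_directly(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(4)
        t = rng.exponential(100, 60)
        e = rng.integers(0, 2, 60)
        curve = km_estimate(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u in curve.times:
            assert curve.at(u) == pytest.approx(
                float(kmf.survival_function_at_times(u).iloc[0]), abs=1e-12
            )


class TestTimeDependentAuc:
    def test_perfect_ranking_is_one(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(10, 100, 50)
        e = np.ones(50, int)
        for u in np.quantile(t, [0.25, 0.5, 0.75]):
            assert td_auc(-t, t, e, u) == pytest.approx(1.0)

    def test_small_uncensored_case_matches_pair_counting(self):
        rng = np.random.default_rng(1)
        t = np.array([3.0, 9.0, 5.0, 12.0, 7.0, 1.0])
        e = np.ones(6, int)
        s = rng.standard_normal(6)
        u = 6.0
        cases = t <= u
        num = den = 0
        for i in np.flatnonzero(cases):
            for j in np.flatnonzero(~cases):
                num += (s[i] > s[j]) + 0.5 * (s[i] == s[j])
                den += 1
        assert td_auc(s, t, e, u) == pytest.approx(num / den)

    def test_matches_scikit_survival_ipcw_estimator(self):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        rng = np.random.default_rng(0)
        n = 250
        true = rng.exponential(500, n)
        c = rng.uniform(100, 900, n)
        t = np.minimum(true, c)
        e = (true <= c).astype(int)
        scores = -np.log(true) + 0.3 * rng.standard_normal(n)
        ts = np.quantile(t[e == 1], [0.2, 0.4, 0.6, 0.8])
        y = Surv.from_arrays(e.astype(bool), t)
        expected, _ = cumulative_dynamic_auc(y, y, scores, ts)
        cc = censoring_km(t, e)
        got = [td_auc(scores, t, e, u, cc) for u in ts]
        assert np.allclose(got, expected, atol=1e-10)

    def test_undefined_when_no_cases(self):
        t = np.array([10.0, 20.0])
        assert np.isnan(td_auc([0.1, 0.2], t, [1, 1], 5.0))


class TestIauc:
    def test_constant_auc_levels(self):
        rng = np.random.default_rng(2)
        t = rng.uniform(10, 100, 200)
        e = np.ones(200, int)
        assert iauc(-t, t, e) == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(300, 150)
        c = rng.uniform(50, 700, 150)
        obs = np.minimum(t, c)
        e = (t <= c).astype(int)
        s = rng.standard_normal(150)
        base = iauc(s, obs, e)
        for f in (np.exp, lambda v: v**3, lambda v: 5 * v - 2):
            assert iauc(f(s), obs, e) == pytest.approx(base, abs=1e-12)

    def test_informative_scores_beat_random(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 400
            x = rng.standard_normal(n)
            t = np.exp(6.0 + 0.8 * x + 0.4 * rng.standard_normal(n))
            c = rng.uniform(100, 1500, n)
            obs, e = np.minimum(t, c), (t <= c).astype(int)
            if iauc(-x, obs, e) > iauc(rng.standard_normal(n), obs, e):
                hits += 1
        assert hits >= 9


class TestRmseUncensored:
    def test_exact_predictions(self):
        assert rmse_uncensored([5.0, 7.0], [5.0, 7.0], [1, 1]) == 0.0

    def test_censored_subjects_excluded(self):
        # errors (3, 100) but the 100 belongs to a censored subject
        assert rmse_uncensored([13.0, 200.0], [10.0, 100.0], [1, 0]) == pytest.approx(3.0)

    def test_two_event_hand_value(self):
        assert rmse_uncensored([13.0, 104.0], [10.0, 100.0], [1, 1]) == pytest.approx(
            np.sqrt(12.5)
        )

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            rmse_uncensored([1.0], [1.0], [0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_censored_predictions(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        obs = rng.uniform(1, 100, n)
        ev = rng.integers(0, 2, n)
        ev[0] = 1  # keep at least one event
        pred = rng.uniform(1, 100, n)
        perturbed = pred.copy()
        perturbed[ev == 0] = rng.uniform(1, 1e6, (ev == 0).sum())
        assert rmse_uncensored(pred, obs, ev) == rmse_uncensored(perturbed, obs, ev)


class TestCrossValidate:
    def test_mean_predictor_closed_form(self, small_cohort):
        ds = small_cohort.with_folds(5, seed=0)

        def fit_predict(train, test):
            mu = train.times[train.events == 1].mean()
            return np.full(test.n, mu)

        report = cross_validate(ds, fit_predict)
        # recompute pooled RMSE by hand from the same held-out predictions
        pred = np.empty(ds.n)
        fold = np.array([ds.folds.assignment[i] for i in ds.ids])
        for f in range(1, 6):
            tr = ds.subset(fold != f)
            pred[fold == f] = tr.times[tr.events == 1].mean()
        expect = rmse_uncensored(pred, ds.times, ds.events)
        assert report.rmse_uncensored == pytest.approx(expect)

    def test_deterministic_repeat(self, small_cohort):
        ds = small_cohort.with_folds(5, seed=1)

        def fit_predict(train, test):
            rng = np.random.default_rng(train.n)
            return rng.uniform(50, 500, test.n)

        a = cross_validate(ds, fit_predict).to_json()
        b = cross_validate(ds, fit_predict).to_json()
        assert a == b
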