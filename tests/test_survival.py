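"""Kaplan-Meier, log-rank, and Cox partial-likelihood machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from wntsig.survival import (
    NonConvergenceError,
    SurvivalRecord,
    cox_fit,
    cox_interaction,
    kaplan_meier,
    logrank_test,
)


def recs(times, events, x=None, prefix="s"):
    return [
        SurvivalRecord(
            f"{prefix}{i}", float(t), int(e),
            {} if x is None else {"x": float(x[i])},
        )
        for i, (t, e) in enumerate(zip(times, events))
    ]


def exact_partial_loglik(beta, times, events, x):
    """Brute-force Cox partial likelihood (no ties assumed)."""
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            risk = [j for j in range(len(times)) if times[j] >= times[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


class TestKaplanMeier:
    def test_no_censoring_empirical_survival(self):
        km = kaplan_meier(recs([1, 2, 3, 4], [1, 1, 1, 1]))
        np.testing.assert_allclose(km["survival"], [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(km["n_at_risk"], [4, 3, 2, 1])

    def test_all_censored_flat_curve(self):
        km = kaplan_meier(recs([1, 2, 3], [0, 0, 0]))
        assert km.empty  # no drops: S stays at 1

    def test_censoring_between_events_hand_computed(self):
        # events at 2 and 5, censor at 3: S(2)=4/5*1, S(5)=4/5*(1-1/2)
        km = kaplan_meier(recs([2, 3, 5, 1, 7], [1, 0, 1, 1, 0]))
        expected = [(1, 4 / 5), (2, 4 / 5 * 3 / 4), (5, 4 / 5 * 3 / 4 * 1 / 2)]
        assert list(km["time"]) == [t for t, _ in expected]
        np.testing.assert_allclose(km["survival"], [s for _, s in expected])

    def test_curve_nonincreasing_in_unit_interval(self, rng):
        t = rng.exponential(10, 60)
        e = rng.binomial(1, 0.6, 60)
        km = kaplan_meier(recs(t, e))
        s = km["survival"].to_numpy()
        assert np.all(np.diff(s) <= 0)
        assert np.all((s >= 0) & (s <= 1))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SurvivalRecord("a", -1.0, 1)


class TestLogrank:
    def test_identical_groups_no_signal(self):
        g = recs([1, 2, 3, 4], [1, 1, 0, 1])
        chi2, p = logrank_test([g, recs([1, 2, 3, 4], [1, 1, 0, 1], prefix="t")])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_convention(self):
        chi2, p = logrank_test([recs([1, 2], [0, 0]), recs([3], [0], prefix="t")])
        assert (chi2, p) == (0.0, 1.0)

    def test_hand_tabulated_observed_minus_expected(self):
        # group A events at 1,2,3; group B events at 10,20,30
        a = recs([1, 2, 3], [1, 1, 1], prefix="a")
        b = recs([10, 20, 30], [1, 1, 1], prefix="b")
        chi2, p = logrank_test([a, b])
        # per-event-time 2x2 tables: O_A, E_A, V accumulated by hand
        n_a, n_b = 3, 3
        O = E = V = 0.0
        for _ in range(3):  # A's events at t=1,2,3 while all of B at risk
            n = n_a + n_b
            O += 1
            E += n_a / n
            V += (n_a / n) * (1 - n_a / n)  # single event: (n-d)/(n-1) = 1
            n_a -= 1
        for _ in range(3):  # B's events after A is exhausted: n_a = 0
            n = n_b
            E += 0.0
            n_b -= 1
        expected_chi2 = (O - E) ** 2 / V
        assert chi2 == pytest.approx(expected_chi2, rel=1e-10)
        assert p == pytest.approx(stats.chi2.sf(expected_chi2, 1), rel=1e-10)

    def test_group_relabeling_invariance(self, rng):
        a = recs(rng.exponential(5, 20), rng.binomial(1, 0.7, 20), prefix="a")
        b = recs(rng.exponential(9, 25), rng.binomial(1, 0.7, 25), prefix="b")
        assert logrank_test([a, b])[0] == pytest.approx(
            logrank_test([b, a])[0], rel=1e-12
        )

    def test_permutation_null_rejection_rate(self):
        # under label permutation the test should reject at ~alpha
        rng = np.random.default_rng(12)
        t = rng.exponential(5, 40)
        e = rng.binomial(1, 0.8, 40)
        rejections = 0
        n_reps = 1000
        for _ in range(n_reps):
            lab = rng.permutation(np.repeat([0, 1], 20))
            g0 = recs(t[lab == 0], e[lab == 0], prefix="a")
            g1 = recs(t[lab == 1], e[lab == 1], prefix="b")
            if logrank_test([g0, g1])[1] < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_reps <= 0.07


class TestCoxFit:
    def test_six_record_toy_matches_grid_search_oracle(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 1, 1, 0]
        x = [1.0, 1.0, 0.0, 1.0, 0.0, 0.0]
        fit = cox_fit(recs(times, events, x), ["x"])
        oracle = optimize.minimize_scalar(
            lambda b: -exact_partial_loglik(b, times, events, x),
            bounds=(-10, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(oracle.x, abs=1e-4)

    def test_loglik_at_estimate_beats_null(self, rng):
        x = rng.binomial(1, 0.5, 50).astype(float)
        t = rng.exponential(np.exp(-0.7 * x))
        fit = cox_fit(recs(t, np.ones(50), x), ["x"])
        assert fit.loglik >= fit.loglik_null

    def test_efron_equals_breslow_without_ties(self, rng):
        t = rng.exponential(5, 40)  # continuous: ties a.s. absent
        e = rng.binomial(1, 0.8, 40)
        x = rng.normal(size=40)
        fe = cox_fit(recs(t, e, x), ["x"], ties="efron")
        fb = cox_fit(recs(t, e, x), ["x"], ties="breslow")
        assert fe.beta[0] == pytest.approx(fb.beta[0], abs=1e-10)

    def test_tied_data_matches_lifelines_efron(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = np.round(rng.exponential(5, 80), 0) + 1
        e = rng.binomial(1, 0.7, 80)
        x = rng.normal(size=80)
        fit = cox_fit(recs(t, e, x), ["x"])
        df = pd.DataFrame({"T": t, "E": e, "x": x})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_null_coverage_of_wald_ci(self):
        # independent labels: beta ~ 0 and the 95% CI covers 0 ~95% of reps
        covered = 0
        n_reps = 200
        for seed in range(n_reps):
            r = np.random.default_rng(seed)
            x = r.binomial(1, 0.5, 500).astype(float)
            t = r.exponential(1.0, 500)
            c = r.uniform(0, 3, 500)
            time = np.minimum(t, c)
            ev = (t <= c).astype(int)
            fit = cox_fit(recs(time, ev, x), ["x"])
            lo, hi = np.log(fit.ci95[0])
            covered += lo <= 0 <= hi
        assert 0.91 <= covered / n_reps <= 0.99

    def test_perfect_separation_raises(self):
        # covariate orders hazard perfectly: monotone likelihood
        t = [1, 2, 3, 4, 10, 11, 12, 13]
        e = [1] * 8
        x = [1, 1, 1, 1, 0, 0, 0, 0]
        with pytest.raises(NonConvergenceError):
            cox_fit(recs(t, e, x), ["x"])

    def test_constant_covariate_and_no_events(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(recs([1, 2, 3], [1, 1, 0], [1, 1, 1]), ["x"])
        with pytest.raises(ValueError, match="event"):
            cox_fit(recs([1, 2, 3], [0, 0, 0], [0, 1, 0]), ["x"])


class TestCoxInteraction:
    def test_constant_interaction_rejected(self):
        records = recs([1, 2, 3, 4], [1, 1, 1, 0], [0.0, 0.0, 1.0, 1.0])
        for r, b in zip(records, [0.0, 1.0, 0.0, 1.0]):
            r.covariates["b"] = b
        for r in records:
            r.covariates["a"] = 0.0  # a == 0 -> a*b constant
        with pytest.raises(ValueError, match="constant"):
            cox_interaction(records, "a", "b")

    def test_null_interaction_p_uniform(self):
        # zero interaction planted: Wald p over seeds ~ U(0,1)
        ps = []
        for seed in range(120):
            r = np.random.default_rng(seed)
            n = 400
            a = r.binomial(1, 0.5, n).astype(float)
            b = r.binomial(1, 0.5, n).astype(float)
            t = r.exponential(np.exp(-(0.5 * a + 0.3 * b)))
            records = recs(t, np.ones(n), a)
            for rec, bv in zip(records, b):
                rec.covariates["b"] = float(bv)
            fit = cox_interaction(records, "x", "b")
            ps.append(fit["x:b"]["wald_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_planted_interaction_recovered(self):
        betas = []
        for seed in range(40):
            r = np.random.default_rng(seed)
            n = 1000
            a = r.binomial(1, 0.5, n).astype(float)
            b = r.binomial(1, 0.5, n).astype(float)
            t = r.exponential(np.exp(-(0.3 * a + 0.2 * b + 1.0 * a * b)))
            records = recs(t, np.ones(n), a)
            for rec, bv in zip(records, b):
                rec.covariates["b"] = float(bv)
            fit = cox_interaction(records, "x", "b")
            betas.append(fit["x:b"]["beta"])
        assert abs(np.median(betas) - 1.0) <= 0.25
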