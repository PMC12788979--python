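"""Unit and property tests for the foundational survival estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from survhte.survival import (fit_cox, harrell_c, kaplan_meier,
                              null_partial_loglik, rmst, rmst_difference,
                              calibration_by_quartile)

from conftest import exponential_arms, exponential_rmst


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_no_events_curve_constant_one(self):
        c = kaplan_meier([1.0, 2.0], [0, 0])
        assert c.times.size == 0
        assert c.survival_at(5.0) == 1.0

    def test_two_events_hand_product_limit(self):
        c = kaplan_meier([1.0, 2.0], [1, 1])
        assert np.allclose(c.survival, [0.5, 0.0])

    def test_matches_brute_force_product_over_risk_sets(self):
        rng = np.random.default_rng(42)
        time = rng.exponential(5.0, 20).round(1)  # rounding forces ties
        event = rng.integers(0, 2, 20)
        event[0] = 1
        c = kaplan_meier(time, event)
        # independent product-limit computation by explicit risk sets
        for i, t in enumerate(c.times):
            prod = 1.0
            for u in np.unique(time[(event == 1) & (time <= t)]):
                n_risk = np.sum(time >= u)
                d = np.sum((time == u) & (event == 1))
                prod *= 1.0 - d / n_risk
            assert c.survival[i] == pytest.approx(prod)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(3)
        time = rng.exponential(10, 150)
        event = (rng.random(150) < 0.7).astype(int)
        c = kaplan_meier(time, event)
        kf = KaplanMeierFitter().fit(time, event)
        for t in np.linspace(0.5, 25, 20):
            assert c.survival_at(t) == pytest.approx(kf.predict(t), abs=1e-12)

    def test_all_events_no_ties_is_empirical_survival(self):
        rng = np.random.default_rng(7)
        time = rng.uniform(0, 10, 25)
        c = kaplan_meier(time, np.ones(25, dtype=int))
        for t in time:
            assert c.survival_at(t) == pytest.approx(np.mean(time > t))

    @pytest.mark.parametrize("time,event,err", [
        ([], [], ValueError), ([-1.0], [1], ValueError), ([1.0], [2], ValueError),
    ])
    def test_invalid_samples_rejected(self, time, event, err):
        with pytest.raises(err):
            kaplan_meier(time, event)


# ---------------------------------------------------------------------------
# RMST
# ---------------------------------------------------------------------------

class TestRMST:
    def test_flat_curve_estimate_tau_se_zero(self):
        r = rmst([10.0, 12.0, 15.0], [0, 0, 0], 6.0)
        assert r.estimate == pytest.approx(6.0)
        assert r.se == 0.0

    def test_hand_integrated_step_function(self):
        r = rmst([1.0, 3.0], [1, 0], 2.0)
        assert r.estimate == pytest.approx(1.0 * 1.0 + 0.5 * 1.0)

    def test_exponential_closed_form(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(10.0, 5000)
        r = rmst(t, np.ones(5000, dtype=int), 24.0)
        assert abs(r.estimate - exponential_rmst(0.1, 24.0)) < 3 * r.se

    def test_se_agrees_with_bootstrap(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(8.0, 400)
        cens = rng.exponential(16.0, 400)
        obs, ev = np.minimum(time, cens), (time <= cens).astype(int)
        r = rmst(obs, ev, 12.0)
        boots = []
        for b in range(300):
            idx = rng.integers(0, 400, 400)
            boots.append(rmst(obs[idx], ev[idx], 12.0).estimate)
        assert r.se == pytest.approx(np.std(boots), rel=0.25)

    def test_tau_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rmst([1.0], [1], 0.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000), st.floats(1.0, 20.0), st.floats(0.1, 10.0))
    def test_monotone_and_lipschitz_in_tau(self, seed, tau, dtau):
        rng = np.random.default_rng(seed)
        time = rng.exponential(5.0, 30)
        event = rng.integers(0, 2, 30)
        a = rmst(time, event, tau).estimate
        b = rmst(time, event, tau + dtau).estimate
        assert a - 1e-9 <= b <= a + dtau + 1e-9


class TestRMSTDifference:
    def test_self_difference_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        d = rmst_difference(t, e, t, e, 3.0)
        assert d.difference == 0.0

    def test_no_events_degenerate(self):
        t = np.array([10.0, 11.0])
        e = np.array([0, 0])
        d = rmst_difference(t, e, t, e, 5.0)
        assert d.difference == 0.0 and d.ci_low == d.ci_high == 0.0

    def test_exponential_arms_close_to_closed_form(self):
        tab = exponential_arms(2000, 0.05, 0.08, seed=9)
        treated = tab[tab.arm == 1]
        control = tab[tab.arm == 0]
        d = rmst_difference(treated.os_time, treated.os_event,
                            control.os_time, control.os_event, 24.0)
        truth = exponential_rmst(0.05, 24.0) - exponential_rmst(0.08, 24.0)
        assert abs(d.difference - truth) < 3 * d.se


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def brute_force_cox_loglik(beta, time, event, x):
    """Efron partial log-likelihood written out explicitly (1 covariate)."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        tied = (time == t) & (event == 1)
        d = tied.sum()
        risk = time >= t
        eta = beta * x
        sum_risk = np.sum(np.exp(eta[risk]))
        sum_tied = np.sum(np.exp(eta[tied]))
        ll += beta * np.sum(x[tied])
        for ell in range(d):
            ll -= np.log(sum_risk - ell / d * sum_tied)
    return ll


class TestCox:
    def test_single_covariate_matches_grid_maximization(self):
        time = np.array([2.0, 3.0, 5.0, 7.0, 11.0, 13.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        tab = pd.DataFrame({"os_time": time, "os_event": event, "x": x})
        fit = fit_cox(tab, "os", ["x"])
        grid = np.linspace(-3, 3, 60001)
        lls = [brute_force_cox_loglik(b, time, event, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert fit.coefs[0] == pytest.approx(beta_star, abs=1e-4)
        assert fit.loglik == pytest.approx(np.max(lls), abs=1e-6)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2)

    def test_empty_model_null_loglik(self):
        tab = exponential_arms(30, 0.1, 0.1, seed=1)
        fit = fit_cox(tab, "os", [])
        assert fit.loglik == pytest.approx(
            null_partial_loglik(tab.os_time, tab.os_event))
        assert fit.aic == pytest.approx(-2 * fit.loglik)

    def test_parameter_recovery_simulation(self):
        # true beta = 0.5 under exponential PH; mean over reps within 3 SE
        reps, n, beta = 60, 800, 0.5
        ests = []
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            x = rng.normal(size=n)
            t = rng.exponential(1.0 / (0.1 * np.exp(beta * x)))
            c = rng.exponential(15.0, n)
            tab = pd.DataFrame({"os_time": np.minimum(t, c),
                                "os_event": (t <= c).astype(int), "x": x})
            ests.append(fit_cox(tab, "os", ["x"]).coefs[0])
        se = np.std(ests) / np.sqrt(reps)
        assert abs(np.mean(ests) - beta) < 3 * se

    def test_affine_rescaling_of_covariate(self):
        tab = exponential_arms(150, 0.05, 0.1, seed=2)
        rng = np.random.default_rng(0)
        tab["x"] = rng.normal(size=len(tab))
        f1 = fit_cox(tab, "os", ["x"])
        tab["x"] = 10.0 * tab["x"]
        f2 = fit_cox(tab, "os", ["x"])
        assert f2.coefs[0] == pytest.approx(f1.coefs[0] / 10.0, rel=1e-5)

    def test_constant_column_rejected(self):
        tab = exponential_arms(20, 0.1, 0.1, seed=3)
        tab["c"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_cox(tab, "os", ["c"])


# ---------------------------------------------------------------------------
# Harrell's c
# ---------------------------------------------------------------------------

def brute_force_c(score, time, event):
    conc = pairs = 0.0
    n = len(score)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            usable = (time[i] < time[j] and event[i] == 1) or \
                     (time[i] == time[j] and event[i] == 1 and event[j] == 0)
            if not usable:
                continue
            pairs += 1
            if score[i] > score[j]:
                conc += 1
            elif score[i] == score[j]:
                conc += 0.5
    return conc / pairs


class TestHarrellC:
    def test_perfect_concordance(self):
        time = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        score = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert harrell_c(score, time, np.ones(5, dtype=int)) == 1.0

    def test_all_tied_scores_half(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        assert harrell_c(np.zeros(4), time, np.ones(4, dtype=int)) == 0.5

    def test_matches_exhaustive_pair_enumeration(self):
        rng = np.random.default_rng(21)
        for rep in range(20):
            n = int(rng.integers(8, 30))
            time = rng.exponential(5, n).round(1)
            event = rng.integers(0, 2, n)
            score = rng.normal(size=n).round(1)
            if not ((event == 1).any()):
                event[0] = 1
            assert harrell_c(score, time, event) == pytest.approx(
                brute_force_c(score, time, event))

    def test_complement_and_monotone_invariance(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(5, 40)
        event = rng.integers(0, 2, 40)
        event[:2] = 1
        score = rng.normal(size=40)
        c = harrell_c(score, time, event)
        assert c + harrell_c(-score, time, event) == pytest.approx(1.0)
        assert harrell_c(np.exp(score), time, event) == pytest.approx(c)

    def test_no_usable_pairs_error(self):
        with pytest.raises(ValueError, match="usable"):
            harrell_c([1.0, 2.0], [1.0, 2.0], [0, 0])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    n = 600
    x = rng.normal(size=n)
    lam = 0.08 * np.exp(0.6 * x)
    t = rng.exponential(1 / lam)
    c = rng.exponential(30, n)
    tab = pd.DataFrame({"os_time": np.minimum(t, c),
                        "os_event": (t <= c).astype(int), "x": x})
    return fit_cox(tab, "os", ["x"]), tab


class TestCalibration:
    def test_predicted_close_to_observed_under_truth(self, fitted):
        fit, tab = fitted
        cal = calibration_by_quartile(fit, tab, "os", 10.0, n_boot=200, seed=4)
        assert len(cal) == 4
        inside = ((cal.predicted >= cal.observed_ci_low) &
                  (cal.predicted <= cal.observed_ci_high))
        assert inside.sum() >= 3  # well-specified model calibrates

    def test_single_resample_degenerate_ci(self, fitted):
        fit, tab = fitted
        cal = calibration_by_quartile(fit, tab, "os", 10.0, n_boot=1, seed=0)
        assert np.allclose(cal.observed_ci_low, cal.observed_ci_high)

    def test_null_model_identical_predictions(self):
        tab = exponential_arms(200, 0.1, 0.1, seed=12)
        rng = np.random.default_rng(1)
        tab["x"] = rng.normal(size=len(tab))
        fit = fit_cox(tab, "os", ["x"])
        fit.coefs = np.zeros_like(fit.coefs)
        cal = calibration_by_quartile(fit, tab, "os", 10.0, n_boot=10, seed=0,
                                      score=rng.normal(size=len(tab)))
        assert cal.predicted.nunique() == 1
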