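"""Tests for the risk-modeling HTE pipeline."""

import itertools

import numpy as np
import pandas as pd
import pytest

from survhte.risk import (PUBLISHED_OS_RISK_COEFS, RiskModel, assign_quartiles,
                          best_subset_cox, finalize_risk_model, quartile_cate,
                          risk_scores, safety_by_quartile, validate_external)
from survhte.survival import CoxFit, fit_cox, harrell_c
from survhte.synthetic import (RiskDependentEffect, default_scenario,
                               simulate_trial, true_quartile_effects)

from conftest import exponential_arms


def ph_data(n, betas, seed, lam0=0.08, cens_scale=25.0):
    """Exponential PH data with named covariate effects."""
    rng = np.random.default_rng(seed)
    cols = {name: rng.normal(size=n) for name in betas}
    lp = sum(b * cols[k] for k, b in betas.items())
    t = rng.exponential(1.0 / (lam0 * np.exp(lp)))
    c = rng.exponential(cens_scale, n)
    return pd.DataFrame({"os_time": np.minimum(t, c),
                         "os_event": (t <= c).astype(int),
                         "arm": rng.binomial(1, 0.5, n), **cols})


class TestBestSubset:
    def test_empty_candidate_set_selects_empty_model(self):
        tab = exponential_arms(50, 0.1, 0.1, seed=0)
        res = best_subset_cox(tab, "os", [])
        assert res.selected == ()
        assert res.n_candidates_evaluated == 1

    def test_matches_exhaustive_enumeration_oracle(self):
        # independent oracle: enumerate subsets with fit_cox, pick min AIC
        tab = ph_data(300, {"a": 0.8, "b": 0.0, "c": 0.0}, seed=3)
        res = best_subset_cox(tab, "os", ["a", "b", "c"])
        oracle = {}
        for r in range(4):
            for subset in itertools.combinations(["a", "b", "c"], r):
                oracle[subset] = fit_cox(tab, "os", list(subset)).aic
        best = min(oracle, key=lambda s: (round(oracle[s], 10), len(s), s))
        assert set(res.selected) == set(best)
        assert res.selected_aic == pytest.approx(oracle[best])

    def test_aic_identity_on_selected_subset(self):
        tab = ph_data(300, {"a": 0.8, "b": 0.0}, seed=4)
        res = best_subset_cox(tab, "os", ["a", "b"])
        refit = fit_cox(tab, "os", list(res.selected))
        assert res.selected_aic == pytest.approx(
            -2 * refit.loglik + 2 * len(res.selected))

    def test_recovers_prognostic_variable(self):
        hits = 0
        sims = 30
        for s in range(sims):
            tab = ph_data(1000, {"a": 1.0, "b": 0.0, "c": 0.0}, seed=1000 + s)
            res = best_subset_cox(tab, "os", ["a", "b", "c"], keep_ledger=False)
            hits += "a" in res.selected
        assert hits >= int(0.95 * sims)

    def test_shared_analysis_set_complete_case(self):
        tab = ph_data(300, {"a": 0.5, "b": 0.2}, seed=6)
        tab.loc[:20, "b"] = np.nan
        res = best_subset_cox(tab, "os", ["a", "b"])
        assert res.analysis_n == len(tab) - 21
        # even the a-only model is fit on the shared (complete-on-b) set
        assert res.ledger[("a",)] != pytest.approx(fit_cox(tab, "os", ["a"]).aic)

    def test_too_many_candidates_guard(self):
        tab = exponential_arms(50, 0.1, 0.1, seed=0)
        with pytest.raises(ValueError, match="20"):
            best_subset_cox(tab, "os", [f"v{i}" for i in range(21)])


class TestRiskModelAndScores:
    def test_finalize_refit_matches_direct_fit(self):
        tab = ph_data(400, {"a": 0.6}, seed=7)
        model = finalize_risk_model(tab, "os", ("a",))
        direct = fit_cox(tab, "os", ["a", "arm"])
        assert np.allclose(model.fit.coefs, direct.coefs)

    def test_empty_subset_gives_treatment_only_model(self):
        tab = ph_data(300, {"a": 0.6}, seed=8)
        model = finalize_risk_model(tab, "os", ())
        assert model.fit.variables == ["arm"]

    def test_treatment_indicator_required(self):
        fit = CoxFit(variables=["a"], coefs=np.array([1.0]), cov=np.eye(1),
                     loglik=0.0, aic=2.0, n=10, n_events=5, converged=True)
        with pytest.raises(ValueError, match="treatment"):
            RiskModel(fit=fit, subset=("a",), outcome="os")

    def test_published_coefficient_scoring_rule(self):
        # a patient differing from reference only by ECOG >= 1 scores the
        # published ECOG log-HR (0.28); scoring ignores recorded arm
        names = list(PUBLISHED_OS_RISK_COEFS) + ["arm"]
        coefs = np.array([*PUBLISHED_OS_RISK_COEFS.values(), -0.05])
        fit = CoxFit(variables=names, coefs=coefs, cov=np.eye(len(names)),
                     loglik=0.0, aic=0.0, n=1200, n_events=998, converged=True)
        model = RiskModel(fit=fit, subset=tuple(PUBLISHED_OS_RISK_COEFS), outcome="os")
        ref = pd.DataFrame({v: [0.0, 0.0] for v in PUBLISHED_OS_RISK_COEFS})
        ref["ecog_ge1"] = [0.0, 1.0]
        ref["arm"] = [0, 1]
        s = risk_scores(model, ref)
        assert s.iloc[0] == pytest.approx(0.0)
        assert s.iloc[1] == pytest.approx(0.28)

    def test_scores_invariant_to_recorded_arm(self):
        tab = ph_data(200, {"a": 0.6}, seed=9)
        model = finalize_risk_model(tab, "os", ("a",))
        s0 = risk_scores(model, tab.assign(arm=0))
        s1 = risk_scores(model, tab.assign(arm=1))
        assert np.allclose(s0, s1)

    def test_missing_covariate_scores_nan(self):
        tab = ph_data(200, {"a": 0.6}, seed=10)
        tab.loc[5, "a"] = np.nan
        model = finalize_risk_model(tab, "os", ("a",))
        s = risk_scores(model, tab)
        assert np.isnan(s.iloc[5]) and s.drop(5).notna().all()


class TestQuartiles:
    def test_eight_distinct_scores(self):
        labels = assign_quartiles([10, 20, 30, 40, 50, 60, 70, 80])
        assert np.array_equal(labels, [1, 1, 2, 2, 3, 3, 4, 4])

    def test_tie_flood_stable_order(self):
        labels = assign_quartiles(np.zeros(10))
        sizes = np.bincount(labels)[1:]
        assert sizes.max() - sizes.min() <= 1
        assert np.array_equal(labels, np.sort(labels))  # stable: input order

    def test_1200_balanced(self):
        rng = np.random.default_rng(0)
        labels = assign_quartiles(rng.normal(size=1200))
        assert np.array_equal(np.bincount(labels)[1:], [300] * 4)

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=101)
        assert np.array_equal(assign_quartiles(s), assign_quartiles(s + 5.0))

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            assign_quartiles([1.0, 2.0, 3.0])


class TestQuartileCate:
    def test_pooled_quartiles_reproduce_ate_weighted(self):
        tab = exponential_arms(600, 0.06, 0.08, seed=12)
        rng = np.random.default_rng(2)
        labels = assign_quartiles(rng.normal(size=len(tab)))
        qe = quartile_cate(tab, labels, "os", 24.0)
        t = qe.table
        w = t.loc[t.group != "ATE", "n"].to_numpy()
        est = t.loc[t.group != "ATE", "estimate"].to_numpy()
        ate = float(t.loc[t.group == "ATE", "estimate"].iloc[0])
        # random labels are arm-balanced on average; weighted mean tracks ATE
        assert np.average(est, weights=w) == pytest.approx(ate, abs=0.8)

    def test_single_arm_quartile_named_error(self):
        tab = exponential_arms(40, 0.05, 0.08, seed=13)
        labels = np.where(tab.arm == 1, 1, 2)
        labels[:20] = np.repeat([3, 4], 10)
        with pytest.raises(ValueError, match="Q"):
            quartile_cate(tab, labels, "os", 24.0)

    def test_risk_dependent_recovery_against_truth(self):
        sc = default_scenario(n=4000, seed=20,
                              effect=RiskDependentEffect(0.55, -0.55))
        trial = simulate_trial(scenario=sc)
        tab = trial.table
        labels = assign_quartiles(trial.truth["lp_os"].to_numpy())
        qe = quartile_cate(tab, labels, "os", 24.0)
        truth = true_quartile_effects(trial, labels, "os")
        est = qe.estimates
        ci = qe.table.loc[qe.table.group != "ATE", ["ci_low", "ci_high"]].to_numpy()
        inside = (truth >= ci[:, 0]) & (truth <= ci[:, 1])
        assert inside.all()
        assert est[3] > est[0]


class TestExternalValidationAndSafety:
    def test_self_validation_equals_in_sample_c(self):
        tab = ph_data(400, {"a": 0.6, "b": -0.4}, seed=14)
        model = finalize_risk_model(tab, "os", ("a", "b"))
        c, cal = validate_external(model, tab, tau=12.0, n_boot=20, seed=0)
        s = risk_scores(model, tab.assign(arm=0))
        expected = harrell_c(s, tab.os_time, tab.os_event)
        assert c == pytest.approx(expected)
        assert len(cal) == 4

    def test_permuted_scores_null_discrimination(self):
        tab = ph_data(2000, {"a": 0.8}, seed=15)
        rng = np.random.default_rng(3)
        s = rng.permutation(tab["a"].to_numpy())
        c = harrell_c(s, tab.os_time, tab.os_event)
        assert c == pytest.approx(0.5, abs=0.03)

    def test_missing_covariate_in_external_rejected(self):
        tab = ph_data(300, {"a": 0.6}, seed=16)
        model = finalize_risk_model(tab, "os", ("a",))
        with pytest.raises(KeyError, match="a"):
            validate_external(model, tab.drop(columns="a"), tau=12.0)

    def test_safety_counts_partition(self):
        trial = simulate_trial(scenario=default_scenario(n=800, seed=21))
        tab = trial.table
        labels = assign_quartiles(trial.truth["lp_os"].to_numpy())
        inc, disc, n_excl = safety_by_quartile(tab, labels)
        assert inc["n"].sum() == len(tab) - n_excl
        # discontinuation proportions sum to 1 per quartile x arm cell
        sums = disc.groupby(["quartile", "arm"])["prop"].sum()
        assert np.allclose(sums, 1.0)

    def test_all_zero_flags_zero_incidence(self):
        tab = exponential_arms(80, 0.05, 0.08, seed=17)
        for f in ("trae_g3_nonheme", "neutropenia_g3", "febrile_neutropenia"):
            tab[f] = 0.0
        tab["discontinuation_reason"] = "completed"
        rng = np.random.default_rng(4)
        inc, disc, n_excl = safety_by_quartile(tab, assign_quartiles(rng.normal(size=len(tab))))
        assert n_excl == 0
        assert (inc.filter(like="_prop") == 0).all().all()

    def test_unknown_discontinuation_category(self):
        tab = exponential_arms(40, 0.05, 0.08, seed=18)
        for f in ("trae_g3_nonheme", "neutropenia_g3", "febrile_neutropenia"):
            tab[f] = 0.0
        tab["discontinuation_reason"] = "vanished"
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="vanished"):
            safety_by_quartile(tab, assign_quartiles(rng.normal(size=len(tab))))

    def test_toxicity_incidence_rises_with_risk(self):
        trial = simulate_trial(scenario=default_scenario(n=6000, seed=22))
        tab = trial.table
        labels = assign_quartiles(trial.truth["lp_os"].to_numpy())
        inc, _, _ = safety_by_quartile(tab, labels)
        by_q = inc.groupby("quartile")["trae_g3_nonheme_count"].sum() / \
            inc.groupby("quartile")["n"].sum()
        assert by_q.loc[4] > by_q.loc[1]
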