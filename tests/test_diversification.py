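import math

import numpy as np
import pytest

from radiad.diversification import (
    BDModel, CovariateCurve, bd_loglik, fit_bd, candidate_models,
    fit_candidates, compare_and_average, akaike_weights, rate_through_time,
    mass_extinction_test, covariate_bd, ltt_to_diversity_curve, adequacy_check,
    ModelSet,
)
from radiad.synth import simulate_bd_tree
from radiad.tree import tree_from_newick

from helpers import bd_loglik_ode_oracle

FINE = 32768  # quadrature grid for high-precision comparisons


class TestLikelihood:
    def test_yule_closed_form(self, bd_tree_10):
        # pure birth, full sampling: L = lam^(n-2) exp(-lam * total length)
        tree = bd_tree_10
        n, tbl = tree.n_tips, tree.total_branch_length()
        lam = 0.17
        m = BDModel("constant", "zero", {"lambda0": lam})
        expected = (n - 2) * math.log(lam) - lam * tbl
        assert bd_loglik(tree, m, method="closed") == pytest.approx(expected, abs=1e-10)
        assert bd_loglik(tree, m, method="quadrature", grid_size=FINE) == pytest.approx(
            expected, abs=1e-8
        )

    def test_constant_bd_quadrature_matches_closed(self, bd_tree_10):
        m = BDModel("constant", "constant", {"lambda0": 0.15, "mu0": 0.05}, rho=0.8)
        closed = bd_loglik(bd_tree_10, m, method="closed")
        quad = bd_loglik(bd_tree_10, m, method="quadrature", grid_size=FINE)
        assert quad == pytest.approx(closed, abs=1e-8)

    def test_ode_oracle_constant(self, bd_tree_10):
        m = BDModel("constant", "constant", {"lambda0": 0.15, "mu0": 0.05}, rho=0.9)
        ll = bd_loglik(bd_tree_10, m)
        oracle = bd_loglik_ode_oracle(
            bd_tree_10, lambda t: 0.15, lambda t: 0.05, rho=0.9
        )
        assert ll == pytest.approx(oracle, abs=1e-6)

    def test_ode_oracle_time_varying(self, bd_tree_10):
        lam0, a = 0.12, -0.04  # speciation rising toward the present
        mu0 = 0.03
        m = BDModel("exponential", "constant",
                    {"lambda0": lam0, "a_lam": a, "mu0": mu0})
        ll = bd_loglik(bd_tree_10, m, grid_size=FINE)
        oracle = bd_loglik_ode_oracle(
            bd_tree_10,
            lambda t: lam0 * math.exp(a * t),
            lambda t: mu0,
        )
        assert ll == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("form", ["linear", "exponential"])
    def test_nested_reduction_to_constant(self, bd_tree_10, form):
        base = BDModel("constant", "constant", {"lambda0": 0.2, "mu0": 0.04})
        nested = BDModel(form, "constant",
                         {"lambda0": 0.2, "a_lam": 0.0, "mu0": 0.04})
        ll_c = bd_loglik(bd_tree_10, base, method="quadrature")
        ll_n = bd_loglik(bd_tree_10, nested)
        assert ll_n == pytest.approx(ll_c, abs=1e-10)

    def test_negative_rates_rejected(self, bd_tree_10):
        m = BDModel("linear", "zero", {"lambda0": 0.05, "a_lam": -0.05})
        with pytest.raises(ValueError, match="negative"):
            bd_loglik(bd_tree_10, m)

    def test_likelihood_independent_of_tip_order(self, bd_tree_10):
        # branching times fully determine the likelihood
        m = BDModel("constant", "constant", {"lambda0": 0.15, "mu0": 0.05})
        newick = bd_tree_10.newick()
        t2 = tree_from_newick(newick)
        assert bd_loglik(t2, m) == pytest.approx(bd_loglik(bd_tree_10, m))


class TestFitting:
    def test_yule_mle_closed_form(self, yule_tree_60):
        tree = yule_tree_60
        lam_ref = (tree.n_tips - 2) / tree.total_branch_length()
        fit = fit_bd(tree, BDModel("constant", "zero"), starts=4, seed=0)
        assert fit.model.params["lambda0"] == pytest.approx(lam_ref, abs=1e-6)

    def test_fit_improves_on_any_start(self, bd_tree_80):
        m = BDModel("constant", "constant")
        fit = fit_bd(bd_tree_80, m, starts=6, seed=1)
        start_model = BDModel("constant", "constant",
                              {"lambda0": 0.3, "mu0": 0.01})
        assert fit.logL >= bd_loglik(bd_tree_80, start_model) - 1e-9

    def test_aicc_formula(self, bd_tree_80):
        fit = fit_bd(bd_tree_80, BDModel("constant", "constant"), starts=4, seed=2)
        n, k = fit.n_obs, fit.k
        expected = -2 * fit.logL + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(expected)


class TestModelAveraging:
    def test_weights_hand_example(self):
        w = akaike_weights([100.0, 102.0])
        assert w == pytest.approx([0.7311, 0.2689], abs=5e-4)

    def test_weights_sum_and_permutation_invariance(self):
        a = [310.2, 305.7, 309.9, 331.0]
        w = akaike_weights(a)
        assert w.sum() == pytest.approx(1.0)
        perm = [2, 0, 3, 1]
        w2 = akaike_weights([a[i] for i in perm])
        assert np.allclose(w2, w[perm])

    def test_single_model_weight_one(self, yule_tree_60):
        fit = fit_bd(yule_tree_60, BDModel("constant", "zero"), starts=3, seed=0)
        out = compare_and_average([fit], eval_age=0.0)
        assert out["weights"] == pytest.approx([1.0])
        assert out["lambda"] == pytest.approx(fit.model.params["lambda0"])

    def test_differing_nobs_rejected(self, yule_tree_60, bd_tree_10):
        f1 = fit_bd(yule_tree_60, BDModel("constant", "zero"), starts=2, seed=0)
        f2 = fit_bd(bd_tree_10, BDModel("constant", "zero"), starts=2, seed=0)
        with pytest.raises(ValueError, match="n_obs"):
            ModelSet([f1, f2])


class TestRateThroughTime:
    def test_constant_is_flat(self, yule_tree_60):
        fit = fit_bd(yule_tree_60, BDModel("constant", "constant"), starts=4, seed=3)
        grid = np.linspace(0, yule_tree_60.crown_age, 20)
        rtt = rate_through_time(fit, grid)
        assert np.allclose(rtt, rtt[0])

    def test_negative_exponent_rises_toward_present(self, yule_tree_60):
        m = BDModel("exponential", "zero", {"lambda0": 0.3, "a_lam": -0.05})
        from radiad.diversification import BDFit
        fit = BDFit(model=m, logL=0.0, k=2, aicc=0.0, n_obs=60,
                    crown_age=yule_tree_60.crown_age, free=("lambda0", "a_lam"))
        grid = np.linspace(0, yule_tree_60.crown_age, 30)  # old -> young
        rtt = rate_through_time(fit, grid)
        assert np.all(np.diff(rtt) < 0)  # decreasing with age = rising to present

    def test_grid_outside_span_errors(self, yule_tree_60):
        fit = fit_bd(yule_tree_60, BDModel("constant", "zero"), starts=2, seed=0)
        with pytest.raises(ValueError):
            rate_through_time(fit, [yule_tree_60.crown_age * 2])


class TestCovariate:
    def test_beta_zero_equals_constant(self, bd_tree_10):
        curve = CovariateCurve([0.0, 50.0], [12.0, 4.0])
        m_cov = BDModel("covariate", "zero", {"lambda0": 0.2, "beta": 0.0},
                        covariate=curve)
        m_const = BDModel("constant", "zero", {"lambda0": 0.2})
        ll_cov = bd_loglik(bd_tree_10, m_cov)
        ll_const = bd_loglik(bd_tree_10, m_const, method="quadrature")
        assert ll_cov == pytest.approx(ll_const, abs=1e-10)

    def test_span_check(self, bd_tree_10):
        short = CovariateCurve([0.0, bd_tree_10.crown_age / 2], [1.0, 2.0])
        with pytest.raises(ValueError, match="span"):
            covariate_bd(bd_tree_10, short)

    def test_ltt_to_diversity_curve(self, tiny_tree):
        curve = ltt_to_diversity_curve(tiny_tree)
        assert float(curve(0.0)) == 3
        assert float(curve(0.5)) == 3
        assert float(curve(1.5)) == 2
        assert float(curve(2.5)) == 1

    def test_recovery_of_covariate_sign(self):
        # speciation tracking a declining-with-age covariate: beta > 0
        curve = CovariateCurve([0.0, 40.0], [10.0, 2.0])
        beta_true = 0.25
        lam = lambda t: 0.03 * np.exp(beta_true * curve(np.asarray(t)))
        hits = 0
        n_rep = 12
        for s in range(n_rep):
            t = simulate_bd_tree(lam, 0.0, stop="age", age=30.0, seed=500 + s,
                                 max_retries=300)
            if t.n_tips < 15:
                continue
            fit = covariate_bd(t, curve, starts=4, seed=s,
                               allow_extrapolation=True)
            hits += fit.model.params["beta"] > 0
        assert hits >= 0.8 * n_rep - 2


class TestMassExtinction:
    def test_t0_outside_span_errors(self, bd_tree_10):
        with pytest.raises(ValueError):
            mass_extinction_test(bd_tree_10, bd_tree_10.crown_age * 2)

    def test_null_tree_shows_no_event(self):
        favoured = 0
        s_hats = []
        for s in range(5):
            t = simulate_bd_tree(0.15, 0.05, stop="age", age=45.0,
                                 seed=900 + s, max_retries=300)
            rep = mass_extinction_test(t, 18.0, starts=4, seed=s)
            favoured += rep.favoured
            s_hats.append(rep.s_hat)
        assert favoured <= 1
        assert np.median(s_hats) > 0.5

    def test_event_reduces_to_base_at_s_one(self, bd_tree_80):
        m = BDModel("constant", "constant", {"lambda0": 0.15, "mu0": 0.05})
        ll_base = bd_loglik(bd_tree_80, m, method="quadrature")
        ll_ev = bd_loglik(bd_tree_80, m, method="quadrature",
                          events=[(bd_tree_80.crown_age / 2, 1.0)])
        assert ll_ev == pytest.approx(ll_base, abs=1e-9)


class TestAdequacy:
    def test_quantiles_within_unit_interval(self, yule_tree_60):
        model = BDModel("constant", "zero",
                        {"lambda0": (yule_tree_60.n_tips - 2)
                         / yule_tree_60.total_branch_length()})
        rep = adequacy_check(yule_tree_60, model, n_sims=100, seed=4)
        for stat in rep["statistics"].values():
            assert 0.0 <= stat["quantile"] <= 1.0

    def test_misfit_flagged_for_increasing_rate_tree(self):
        lam = lambda t: 0.30 * np.exp(-0.10 * np.asarray(t))
        tree = None
        for s in range(200):
            cand = simulate_bd_tree(lam, 0.0, stop="age", age=30.0,
                                    seed=40 + s, max_retries=200)
            if cand.n_tips >= 40:
                tree = cand
                break
        # a constant-rate model fitted to a strongly accelerating tree
        fit = fit_bd(tree, BDModel("constant", "zero"), starts=3, seed=0)
        rep = adequacy_check(tree, fit.model, n_sims=100, seed=5,
                             tip_window=(0.3, 3.0))
        assert rep["statistics"]["gamma"]["quantile"] > 0.97
        assert not rep["adequate"]


def test_candidate_set_runs_and_averages(bd_tree_80):
    ms = fit_candidates(bd_tree_80, candidate_models()[:4], starts=4, seed=11)
    out = compare_and_average(ms, eval_age=0.0)
    assert out["lambda"] > 0
    assert sum(out["weights"]) == pytest.approx(1.0)
    assert len(out["table"]) == 4
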