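"""MLE fitting, inference, effect sizes, and information criteria."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from hypothesis import given, settings
from hypothesis import strategies as st

from kinergm import (
    KinNetwork,
    ModelSpec,
    NodeTable,
    build_design,
    edges,
    fit_model,
    fold_change,
    generate_attributes,
    information_criteria,
    nodematch,
    simulate_network,
    theta_for_fold,
)
from kinergm.fit import fit_grouped, group_design


class TestInterceptOnly:
    def test_mle_is_logit_of_density(self):
        nodes = NodeTable(["1", "2", "3"])
        net = KinNetwork.from_edges(nodes, [("1", "2")])
        res = fit_model(build_design(net, ModelSpec([edges()])))
        assert res.params[0] == pytest.approx(math.log((1 / 3) / (2 / 3)), abs=1e-8)

    def test_density_recovered_exactly(self, sexmatch_net):
        net, _, _ = sexmatch_net
        res = fit_model(build_design(net, ModelSpec([edges()])))
        assert expit(res.params[0]) == pytest.approx(net.density, abs=1e-10)


class TestOracleEquivalence:
    def test_matches_statsmodels_glm(self, sexmatch_net):
        net, spec, _ = sexmatch_net
        design = build_design(net, spec)
        res = fit_model(design)
        glm = sm.GLM(design.y, design.X, family=sm.families.Binomial()).fit()
        assert np.allclose(res.params, glm.params, atol=1e-6)
        assert res.loglik == pytest.approx(glm.llf, abs=1e-6)
        assert np.allclose(res.se, glm.bse, atol=1e-6)

    def test_matches_generic_optimizer(self, sexmatch_net):
        net, spec, _ = sexmatch_net
        design = build_design(net, spec)
        res = fit_model(design)
        X, y = design.X, design.y.astype(float)

        def nll(beta):
            eta = X @ beta
            return -(y @ eta - np.logaddexp(0.0, eta).sum())

        opt = minimize(nll, np.zeros(X.shape[1]), method="BFGS",
                       options={"gtol": 1e-10})
        assert np.allclose(res.params, opt.x, atol=1e-6)

    def test_grouped_fit_identical_to_dyad_level(self, sexmatch_net):
        net, spec, _ = sexmatch_net
        design = build_design(net, spec)
        res = fit_model(design)
        Xp, inv, trials = group_design(design.X)
        s = np.bincount(inv, weights=design.y.astype(float))
        res_g = fit_grouped(Xp, s, trials, design.columns)
        assert np.allclose(res.params, res_g.params, atol=1e-10)
        assert res.loglik == pytest.approx(res_g.loglik, abs=1e-8)
        assert np.allclose(res.se, res_g.se, atol=1e-10)
        assert res_g.n_dyads == design.n_dyads


def test_parameter_recovery_in_simulation():
    """Mean match-coefficient estimate over 200 draws is within 3 MC SEs of truth."""
    nodes = generate_attributes(300, {"sex": (["1", "2"], [0.5, 0.5])}, seed=0)
    spec = ModelSpec([edges(), nodematch("sex")])
    truth = np.array([-4.0, 0.5])
    estimates = []
    for r in range(200):
        net = simulate_network(nodes, spec, truth, seed=1000 + r)
        estimates.append(fit_model(build_design(net, spec)).params[1])
    estimates = np.array(estimates)
    mc_se = estimates.std(ddof=1) / math.sqrt(len(estimates))
    assert abs(estimates.mean() - truth[1]) < 3 * mc_se


class TestFoldChange:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.35, 1.41), (0.30, 1.34), (1.0, 2.64)],
    )
    def test_printed_values_at_baseline_minus4(self, theta, expected):
        assert round(fold_change(-4.0, theta), 2) == expected

    def test_quarter_effect_near_1p27(self):
        # the closed form gives 1.2775, conventionally reported as about 1.27
        assert fold_change(-4.0, 0.25) == pytest.approx(1.27, abs=0.01)

    def test_zero_effect_is_identity(self):
        assert fold_change(-1.2345, 0.0) == 1.0

    @settings(deadline=None, derandomize=True)
    @given(
        theta0=st.floats(-10, 2),
        t1=st.floats(-3, 3),
        dt=st.floats(0.01, 2),
    )
    def test_strictly_increasing_in_theta(self, theta0, t1, dt):
        assert fold_change(theta0, t1 + dt) > fold_change(theta0, t1)

    def test_tends_to_odds_ratio_in_sparse_limit(self):
        assert fold_change(-30.0, 0.7) == pytest.approx(math.exp(0.7), rel=1e-6)

    def test_inverse(self):
        theta = theta_for_fold(-9.0, 549.0)
        assert fold_change(-9.0, theta) == pytest.approx(549.0, rel=1e-10)
        with pytest.raises(ValueError):
            theta_for_fold(-4.0, 100.0)   # fold above the 1/p0 cap

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            fold_change(float("nan"), 0.1)


class TestInformationCriteria:
    def test_direct_formula(self):
        ic = information_criteria(-100.0, 2, 44850)
        assert ic.bic == pytest.approx(200 + 2 * math.log(44850), abs=1e-6)
        assert ic.aic == pytest.approx(204.0)

    def test_aicc_converges_to_aic(self):
        ic = information_criteria(-100.0, 2, 44850)
        assert 0 < ic.aicc - ic.aic < 1e-3
        small = information_criteria(-100.0, 2, 10)
        assert small.aicc - small.aic > 1.0

    def test_zero_parameter_edge_case(self):
        ic = information_criteria(-50.0, 0, 100)
        assert ic.bic == ic.aic == ic.aicc == 100.0

    def test_aicc_undefined_for_tiny_samples(self):
        assert math.isnan(information_criteria(-5.0, 3, 4).aicc)


def test_adding_a_column_never_decreases_loglik(sexmatch_net):
    net, spec, _ = sexmatch_net
    ll_small = fit_model(build_design(net, ModelSpec([edges()]))).loglik
    ll_big = fit_model(build_design(net, spec)).loglik
    assert ll_big >= ll_small - 1e-10


def test_loglik_is_nonpositive(sexmatch_net):
    net, spec, _ = sexmatch_net
    assert fit_model(build_design(net, spec)).loglik <= 0


class TestDegenerateDesigns:
    def test_separation_flagged_others_reported(self):
        # all matched dyads are edges, no unmatched dyad is: perfect separation
        nodes = NodeTable(
            [str(k) for k in range(8)],
            {"sex": ["1"] * 4 + ["2"] * 4},
        )
        matched = [
            (str(a), str(b))
            for a in range(8)
            for b in range(a + 1, 8)
            if (a < 4) == (b < 4)
        ]
        net = KinNetwork.from_edges(nodes, matched)
        res = fit_model(build_design(net, ModelSpec([edges(), nodematch("sex")])))
        assert res.separated[1]
        assert not res.converged
        assert math.isinf(res.se[1])
        assert math.isnan(res.pvalues[1])

    def test_collinear_columns_named(self, sexmatch_net):
        net, spec, _ = sexmatch_net
        design = build_design(net, spec)
        design.X = np.column_stack([design.X, design.X[:, 1]])
        design.columns = design.columns + ["nodematch.sex.copy"]
        with pytest.raises(ValueError, match="nodematch.sex"):
            fit_model(design)

    def test_constant_column_rejected(self, sexmatch_net):
        net, spec, _ = sexmatch_net
        design = build_design(net, spec)
        design.X = design.X.copy()
        design.X[:, 1] = 0.0
        with pytest.raises(ValueError, match="constant"):
            fit_model(design)
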