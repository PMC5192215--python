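"""Multi-regime BM/OU likelihoods, fitting, and ensemble summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from phyloenv.comparative import pgls_fit
from phyloenv.ou import (
    OUModelSpec, compare_models, ensemble_fit, fit_ou, ou_loglik, ou_moments,
    relative_brain_residuals,
)
from phyloenv.synthetic import (
    er_rate_matrix, scale_tree, simulate_allometric_dataset,
    simulate_regime_history, simulate_trait,
)
from phyloenv.trees import phylo_covariance, read_newick, simulate_yule_tree


def single_regime_history(tree, seed=0):
    return simulate_regime_history(tree, np.zeros((1, 1)), 0, seed=seed,
                                   state_labels=["only"])


class TestMoments:
    def test_small_alpha_limit_is_brownian(self, yule50):
        h = single_regime_history(yule50)
        C = phylo_covariance(yule50).matrix
        mu, V = ou_moments(h, OUModelSpec("OU1", theta=0.7, alpha=1e-8, sigma2=0.4))
        assert np.allclose(mu, 0.7, atol=1e-6)       # root sits at the optimum
        assert np.allclose(V, 0.4 * C, rtol=1e-5)

    def test_single_branch_closed_form(self):
        t = read_newick("(A:1.3);")
        h = simulate_regime_history(t, np.zeros((2, 2)), 1, seed=0)  # regime 2 throughout
        alpha, theta = 0.9, np.array([0.0, 2.0])
        mu, V = ou_moments(h, OUModelSpec("OUM", theta=theta, alpha=alpha, sigma2=1.0))
        # x0 = theta_root = 2 here, so the mean stays at 2
        assert mu[0] == pytest.approx(2.0, abs=1e-12)
        spec_free = OUModelSpec("OUM", theta=theta, alpha=alpha, sigma2=1.0,
                                root="free", x0=5.0)
        mu_f, _ = ou_moments(h, spec_free)
        assert mu_f[0] == pytest.approx(2.0 + (5.0 - 2.0) * np.exp(-alpha * 1.3), abs=1e-12)
        assert V[0, 0] == pytest.approx(1.0 * -np.expm1(-2 * alpha * 1.3) / (2 * alpha), abs=1e-12)

    def test_nonultrametric_rejected_under_ou(self):
        t = read_newick("((A:1,B:2):1,C:2);")
        h = single_regime_history(t)
        with pytest.raises(ValueError, match="ultrametric"):
            ou_moments(h, OUModelSpec("OU1", theta=0.0, alpha=1.0, sigma2=1.0))


class TestLoglik:
    def test_two_tip_bm_closed_form(self):
        t = read_newick("(A:1,B:1);")
        h = single_regime_history(t)
        spec = OUModelSpec("BM1", theta=0.3, alpha=0.0, sigma2=0.7)
        x = np.array([0.1, -0.2])
        want = multivariate_normal([0.3, 0.3], 0.7 * np.eye(2)).logpdf(x)
        assert ou_loglik(h, x, spec) == pytest.approx(want, abs=1e-10)

    def test_oum_with_equal_optima_equals_ou1(self, painted_five_tip):
        x = simulate_trait(painted_five_tip, 0.2, 1.0, 0.3, seed=5)
        a = ou_loglik(painted_five_tip, x, OUModelSpec("OUM", theta=[0.2, 0.2], alpha=1.0, sigma2=0.3))
        b = ou_loglik(painted_five_tip, x, OUModelSpec("OU1", theta=0.2, alpha=1.0, sigma2=0.3))
        assert a == pytest.approx(b, abs=1e-9)

    def test_change_of_scale(self, painted_five_tip):
        x = simulate_trait(painted_five_tip, 0.1, 1.0, 0.3, seed=6)
        c = 3.0
        base = ou_loglik(painted_five_tip, x, OUModelSpec("OUM", theta=[0.1, 0.1], alpha=1.0, sigma2=0.3))
        scaled = ou_loglik(
            painted_five_tip, c * x,
            OUModelSpec("OUM", theta=[0.1 * c, 0.1 * c], alpha=1.0, sigma2=0.3 * c * c),
        )
        assert scaled == pytest.approx(base - len(x) * np.log(c), abs=1e-9)

    def test_invariant_to_tip_order(self, painted_five_tip):
        x = simulate_trait(painted_five_tip, 0.0, 1.0, 0.2, seed=7)
        spec = OUModelSpec("OU1", theta=0.0, alpha=1.0, sigma2=0.2)
        shuffled = x.sample(frac=1.0, random_state=1)
        assert ou_loglik(painted_five_tip, shuffled, spec) == pytest.approx(
            ou_loglik(painted_five_tip, x, spec), abs=1e-12
        )

    def test_ou_converges_to_bm(self, yule50):
        h = single_regime_history(yule50)
        x = simulate_trait(h, 0.0, 0.0, 0.5, root_value=0.4, seed=8)
        bm = ou_loglik(h, x, OUModelSpec("BM1", theta=0.4, alpha=0.0, sigma2=0.5))
        ou = ou_loglik(h, x, OUModelSpec("OU1", theta=0.4, alpha=1e-6 * yule50.depth, sigma2=0.5))
        assert abs(ou - bm) / abs(bm) < 1e-4


class TestFitting:
    def test_ou1_equals_oum_on_single_regime_history(self, yule50):
        h = single_regime_history(scale_tree(yule50, 1.0))
        x = simulate_trait(h, 0.3, 2.0, 0.1, root_value=0.3, seed=9)
        f1 = fit_ou(h, x, "OU1")
        f2 = fit_ou(h, x, "OUM")
        assert abs(f1.loglik - f2.loglik) < 1e-6
        assert f1.n_params == 3 and f2.n_params == 3  # single regime: OUM collapses

    def test_bm_data_prefers_bm(self):
        """BM-generated data keeps BM1 within 2 AICc of the best family."""
        hits = 0
        for seed in range(10):
            tree = scale_tree(simulate_yule_tree(200, seed=seed + 200), 1.0)
            h = simulate_regime_history(tree, er_rate_matrix(2, 0.5), 0, seed=seed)
            x = simulate_trait(h, None, 0.0, 0.08, root_value=0.0, seed=seed + 1)
            fits = [fit_ou(h, x, fam) for fam in ("BM1", "OU1", "OUM")]
            best = min(f.aicc for f in fits)
            hits += fits[0].aicc - best <= 2.0
        assert hits >= 8

    def test_aicc_exceeds_aic_and_bic_reported(self, painted_five_tip):
        x = simulate_trait(painted_five_tip, 0.0, 1.0, 0.2, seed=10)
        f = fit_ou(painted_five_tip, x, "BM1")
        aic = -2 * f.loglik + 2 * f.n_params
        assert f.aicc > aic and np.isfinite(f.bic)

    def test_oumva_gated_behind_flag(self, painted_five_tip):
        x = simulate_trait(painted_five_tip, 0.0, 1.0, 0.2, seed=11)
        with pytest.raises(ValueError, match="OUMVA"):
            fit_ou(painted_five_tip, x, "OUMVA")
        f = fit_ou(painted_five_tip, x, "OUMVA", allow_oumva=True)
        assert f.family == "OUMVA" and np.isfinite(f.loglik)

    def test_compare_models_table(self, painted_five_tip):
        x = simulate_trait(painted_five_tip, [0.0, 0.4], 2.0, 0.1, seed=12)
        fits = [fit_ou(painted_five_tip, x, fam) for fam in ("BM1", "OU1", "OUM")]
        tab = compare_models(fits)
        assert tab["weight"].sum() == pytest.approx(1.0)
        # weight ordering matches AICc ordering
        assert (tab["aicc"].is_monotonic_increasing
                and tab["weight"].is_monotonic_decreasing)
        single = compare_models([fits[0]])
        assert single["weight"].iloc[0] == pytest.approx(1.0)


class TestEnsemble:
    def test_identical_maps_zero_theta_se(self, yule50):
        tree = scale_tree(yule50, 1.0)
        h = simulate_regime_history(tree, er_rate_matrix(2, 0.5), 0, seed=13)
        x = simulate_trait(h, [0.0, 0.3], 2.0, 0.05, seed=14)
        summ = ensemble_fit([h, h, h], x, families=("BM1", "OU1", "OUM"))
        assert summ.mean_weights.sum() == pytest.approx(1.0, abs=1e-9)
        oum = summ.theta_summary[summ.theta_summary["family"] == "OUM"]
        assert (oum["se"] < 1e-12).all()

    def test_distinct_optima_separate_across_maps(self):
        tree = scale_tree(simulate_yule_tree(150, seed=300), 1.0)
        h = simulate_regime_history(tree, er_rate_matrix(2, 0.5), 0, seed=15)
        x = simulate_trait(h, [0.0, 0.5], 3.0, 0.03, seed=16)
        from phyloenv.regimes import stochastic_map, fit_mk
        mk = fit_mk(tree, h.tip_states(), state_labels=h.state_labels)
        maps = stochastic_map(tree, h.tip_states(), mk.Q, 10, seed=17,
                              state_labels=h.state_labels)
        summ = ensemble_fit(maps, x, families=("BM1", "OU1", "OUM"))
        oum = summ.theta_summary[summ.theta_summary["family"] == "OUM"].set_index("regime")
        assert oum.loc["S1", "q2.5"] > oum.loc["S0", "q97.5"]


class TestResiduals:
    def test_exact_allometry_gives_zero_residuals(self, yule50):
        df = simulate_allometric_dataset(yule50, sigma2_resid=0.0, seed=18)
        res = relative_brain_residuals(df["log_brain"], df["log_body"], yule50)
        assert np.abs(res).max() < 1e-8

    def test_gls_weighted_mean_zero(self, yule50):
        df = simulate_allometric_dataset(yule50, seed=19)
        fit = pgls_fit(df["log_brain"], df[["log_body"]], yule50)
        from phyloenv.trees import lambda_transform
        V = lambda_transform(phylo_covariance(yule50), fit.lambda_hat).matrix
        r = fit.residuals.loc[list(yule50.tip_labels)].to_numpy()
        assert abs(np.ones(len(r)) @ np.linalg.solve(V, r)) < 1e-8

    def test_perturbation_follows_hat_matrix(self, yule50):
        """Raising one species' brain by d raises its residual by d(1 - h_ii)
        where h is the GLS hat matrix at the same lambda."""
        df = simulate_allometric_dataset(yule50, seed=20)
        fit = pgls_fit(df["log_brain"], df[["log_body"]], yule50)
        sp = list(yule50.tip_labels)[7]
        d = 0.1
        bumped = df["log_brain"].copy()
        bumped[sp] += d
        fit2 = pgls_fit(bumped, df[["log_body"]], yule50, lambda_=fit.lambda_hat)
        from phyloenv.trees import lambda_transform
        V = lambda_transform(phylo_covariance(yule50), fit.lambda_hat).matrix
        Vi = np.linalg.inv(V)
        X = np.column_stack([np.ones(len(df)), df.loc[list(yule50.tip_labels), "log_body"]])
        H = X @ np.linalg.solve(X.T @ Vi @ X, X.T @ Vi)
        i = list(yule50.tip_labels).index(sp)
        got = fit2.residuals[sp] - fit.residuals[sp]
        assert got == pytest.approx(d * (1 - H[i, i]), abs=1e-9)
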