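"""PGLS with ML lambda, phylogenetic PCA, and AICc model selection."""

import numpy as np
import pandas as pd
import pytest

from phyloenv.comparative import (
    aicc_from_loglik, akaike_weights, model_selection, pgls_fit, pgls_r2, phylo_pca,
)
from phyloenv.synthetic import scale_tree, simulate_allometric_dataset
from phyloenv.trees import phylo_covariance, lambda_transform, simulate_yule_tree
from conftest import star_tree


def _dataset(n=60, seed=0, lam=0.7, slope=0.5):
    tree = scale_tree(simulate_yule_tree(n, seed=seed), 1.0)
    df = simulate_allometric_dataset(tree, beta1=slope, lambda_resid=lam,
                                     sigma2_resid=0.05, seed=seed + 1)
    return tree, df


class TestPGLS:
    def test_lambda_zero_equals_ols(self):
        tree, df = _dataset(seed=3)
        fit = pgls_fit(df["log_brain"], df[["log_body"]], tree, lambda_=0.0)
        y = df.loc[list(tree.tip_labels), "log_brain"].to_numpy()
        X = np.column_stack([np.ones(len(df)), df.loc[list(tree.tip_labels), "log_body"]])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.params["estimate"].to_numpy(), beta, atol=1e-8)

    def test_perfect_fit_has_unit_r2(self):
        tree, df = _dataset(seed=4)
        y = 1.0 + 2.0 * df["log_body"]
        fit = pgls_fit(y, df[["log_body"]], tree)
        assert np.abs(fit.residuals).max() < 1e-8
        assert fit.r2 == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_explicit_gls_matrix_oracle(self, seed):
        """beta-hat equals (X'V^-1 X)^-1 X'V^-1 y computed by explicit
        inversion at the fitted lambda (n <= 25)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 26))
        tree = simulate_yule_tree(n, seed=seed + 500)
        C = phylo_covariance(tree)
        y = pd.Series(rng.normal(size=n), index=tree.tip_labels)
        X = pd.DataFrame(rng.normal(size=(n, 2)), index=tree.tip_labels, columns=["a", "b"])
        fit = pgls_fit(y, X, tree)
        V = lambda_transform(C, fit.lambda_hat).matrix
        Vi = np.linalg.inv(V)
        Xm = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.solve(Xm.T @ Vi @ Xm, Xm.T @ Vi @ y.to_numpy())
        assert np.allclose(fit.params["estimate"].to_numpy(), beta, atol=1e-8)

    def test_ml_lambda_dominates_endpoints(self):
        tree, df = _dataset(seed=5, lam=0.6)
        fit = pgls_fit(df["log_brain"], df[["log_body"]], tree)
        for fixed in (0.0, 1.0):
            assert fit.loglik >= pgls_fit(
                df["log_brain"], df[["log_body"]], tree, lambda_=fixed
            ).loglik - 1e-6

    def test_statistics_are_sane(self):
        tree, df = _dataset(seed=6)
        fit = pgls_fit(df["log_brain"], df[["log_body"]], tree)
        assert (fit.params["se"] > 0).all()
        assert fit.params["p"].between(0, 1).all()
        assert 0.0 <= fit.lambda_hat <= 1.0
        assert fit.aicc > -2 * fit.loglik + 2 * (fit.p + 2) - 1e-9  # AICc > AIC

    def test_missing_data_dropped_and_reported(self):
        tree, df = _dataset(seed=7)
        df = df.copy()
        sp = df.index[3]
        df.loc[sp, "log_body"] = np.nan
        fit = pgls_fit(df["log_brain"], df[["log_body"]], tree)
        assert fit.n == len(df) - 1 and sp in fit.dropped

    def test_singular_design_raises(self):
        tree, df = _dataset(seed=8)
        X = df[["log_body"]].copy()
        X["dup"] = X["log_body"]
        with pytest.raises(np.linalg.LinAlgError):
            pgls_fit(df["log_brain"], X, tree, lambda_=0.5)


class TestR2:
    def test_partial_zero_when_models_equal(self):
        tree, df = _dataset(seed=9)
        fit = pgls_fit(df["log_brain"], df[["log_body"]], tree)
        full, partial = pgls_r2(fit, fit)
        assert partial == pytest.approx(0.0, abs=1e-12)

    def test_null_environment_effect_gives_tiny_partial_r2(self):
        """Body size explains nearly everything; an unrelated predictor adds
        almost nothing once body size is removed."""
        tree, df = _dataset(n=150, seed=10)
        rng = np.random.default_rng(11)
        df = df.copy()
        df["noise_env"] = rng.normal(size=len(df))
        full = pgls_fit(df["log_brain"], df[["log_body", "noise_env"]], tree)
        reduced = pgls_fit(df["log_brain"], df[["log_body"]], tree)
        r2, partial = pgls_r2(full, reduced)
        assert r2 > 0.8 and partial < 0.1

    def test_non_nested_rejected(self):
        tree, df = _dataset(seed=12)
        rng = np.random.default_rng(0)
        df = df.copy()
        df["other"] = rng.normal(size=len(df))
        a = pgls_fit(df["log_brain"], df[["log_body"]], tree)
        b = pgls_fit(df["log_brain"], df[["other"]], tree)
        with pytest.raises(ValueError, match="nested"):
            pgls_r2(a, b)


class TestPPCA:
    def test_star_tree_equals_ordinary_pca(self):
        star = star_tree(40)
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 3)), index=star.tip_labels,
                         columns=list("abc"))
        res = phylo_pca(X, star, mode="covariance")
        ev = np.sort(np.linalg.eigvalsh(np.cov((X - X.mean()).T.to_numpy())))[::-1]
        assert np.allclose(res.variance_explained, ev / ev.sum(), atol=1e-8)

    def test_duplicate_variables_load_equally(self, yule50):
        rng = np.random.default_rng(1)
        base = rng.normal(size=50)
        X = pd.DataFrame({"v1": base, "v2": base, "v3": rng.normal(size=50)},
                         index=yule50.tip_labels)
        res = phylo_pca(X, yule50, mode="covariance")
        assert abs(res.loadings.loc["v1", "PC1"] - res.loadings.loc["v2", "PC1"]) < 1e-8

    def test_variance_shares_and_score_orthogonality(self, yule50):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(50, 4)), index=yule50.tip_labels)
        res = phylo_pca(X, yule50)
        ve = res.variance_explained
        assert np.all(ve >= 0) and np.all(np.diff(ve) <= 1e-12)
        assert ve.sum() == pytest.approx(1.0)
        C = phylo_covariance(yule50).matrix
        S = res.scores.to_numpy()
        G = S.T @ np.linalg.inv(C) @ S
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8

    def test_dominant_latent_factor_share_recovered(self):
        """Three variables driven by one latent factor: PC1's share matches
        the construction's variance share."""
        star = star_tree(800)
        rng = np.random.default_rng(3)
        latent = rng.normal(size=800)
        noise_sd = 0.35
        X = pd.DataFrame(
            {f"v{i}": latent + rng.normal(0, noise_sd, 800) for i in range(3)},
            index=star.tip_labels,
        )
        res = phylo_pca(X, star, mode="correlation")
        rho = 1.0 / (1.0 + noise_sd**2)       # common correlation
        expected = (1 + 2 * rho) / 3          # top eigenvalue share of a 3x3 equicorrelation
        assert res.variance_explained[0] == pytest.approx(expected, abs=0.03)

    def test_constant_variable_rejected_in_correlation_mode(self, yule50):
        X = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)},
                         index=yule50.tip_labels)
        with pytest.raises(ValueError, match="constant"):
            phylo_pca(X, yule50, mode="correlation")


class TestModelSelection:
    def test_aicc_formula(self):
        assert aicc_from_loglik(-50.0, 3, 100) == pytest.approx(106.25)

    def test_weights_for_known_deltas(self):
        w = akaike_weights(np.array([0.0, 2.0]))
        assert np.allclose(w, [0.731, 0.269], atol=5e-4)
        w = akaike_weights(np.array([0.0, 4.0]))
        assert np.allclose(w, [0.881, 0.119], atol=5e-4)

    def test_importance_separates_signal_from_noise(self):
        tree, df = _dataset(n=200, seed=20, slope=0.59)
        rng = np.random.default_rng(21)
        cand = pd.DataFrame(index=df.index)
        cand["noise"] = rng.normal(size=len(df))
        # a predictor genuinely correlated with the response
        cand["signal"] = df["log_brain"] - 0.59 * df["log_body"] + rng.normal(0, 0.05, len(df))
        tab = model_selection(df["log_brain"], cand, tree, forced=df[["log_body"]])
        assert tab.models["weight"].sum() == pytest.approx(1.0)
        assert tab.importance.between(0, 1).all()
        assert tab.importance["signal"] > tab.importance["noise"]

    def test_noise_importance_low_across_replicates(self):
        hits = 0
        for seed in range(10):
            tree, df = _dataset(n=120, seed=40 + seed)
            rng = np.random.default_rng(seed)
            cand = pd.DataFrame({"noise": rng.normal(size=len(df))}, index=df.index)
            tab = model_selection(df["log_brain"], cand, tree, forced=df[["log_body"]])
            hits += tab.importance["noise"] < 0.5
        assert hits >= 8
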