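import numpy as np
import pandas as pd
import pytest

import hexaflora as hf
from hexaflora.models import ModelComparisonError, ModelSpec, _ProfileGLS


def _star_cov(n):
    return hf.PhyloCov([f"t{i}" for i in range(n)], np.eye(n))


def _ols(X, y):
    """Reference OLS via statsmodels (independent implementation)."""
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(X)).fit()


class TestAgainstOLS:
    """At λ=0 — or on a star tree at any λ — PGLS must reduce to OLS."""

    @pytest.mark.parametrize("case", ["lambda0", "star"])
    def test_reduces_to_ols(self, case):
        rng = np.random.default_rng(13)
        n = 60
        x = rng.normal(size=n)
        y = 0.3 + 0.7 * x + rng.normal(size=n) * 0.4
        if case == "lambda0":
            cov = hf.phylo_cov(hf.sim_tree(n, seed=14))
            est = hf.PGLSRegression(cov=cov, lam=0.0).fit(x, y)
        else:
            est = hf.PGLSRegression(cov=_star_cov(n), lam=0.73).fit(x, y)
        ref = _ols(x, y)
        np.testing.assert_allclose(est.beta_, ref.params, atol=1e-8)
        np.testing.assert_allclose(est.bse_, ref.bse, atol=1e-8)
        np.testing.assert_allclose(est.tvalues_, ref.tvalues, atol=1e-8)
        np.testing.assert_allclose(est.pvalues_, ref.pvalues, atol=1e-8)


class TestAgainstMatrixFormula:
    def test_gls_matches_direct_inverse(self):
        """β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y computed with an explicit inverse."""
        rng = np.random.default_rng(15)
        for seed in range(3):
            tree = hf.sim_tree(50, seed=30 + seed)
            cov = hf.phylo_cov(tree)
            X = rng.normal(size=(50, 2))
            y = rng.normal(size=50)
            for lam in (0.0, 0.4, 1.0):
                est = hf.PGLSRegression(cov=cov, lam=lam).fit(X, y)
                V = cov.with_lambda(lam)
                Vi = np.linalg.inv(V)
                Xd = np.column_stack([np.ones(50), X])
                beta = np.linalg.solve(Xd.T @ Vi @ Xd, Xd.T @ Vi @ y)
                e = y - Xd @ beta
                s2 = (e @ Vi @ e) / (50 - 3)
                se = np.sqrt(np.diag(s2 * np.linalg.inv(Xd.T @ Vi @ Xd)))
                np.testing.assert_allclose(est.beta_, beta, atol=1e-8)
                np.testing.assert_allclose(est.bse_, se, atol=1e-8)


class TestAgainstExternalReference:
    """Frozen values from an independent reference stack (ape/nlme corPagel
    with ML, and phytools phylosig) on the 20-taxon fixture tree."""

    def test_ml_lambda_regression(self, oracle_cov, oracle_traits):
        est = hf.PGLSRegression(cov=oracle_cov).fit(
            oracle_traits[["x"]], oracle_traits["y"])
        assert est.lambda_ == pytest.approx(0.80799232, abs=2e-6)
        np.testing.assert_allclose(
            est.beta_, [0.1079776442, 0.4244234756], atol=1e-6)
        np.testing.assert_allclose(
            est.bse_, [0.0256050901, 0.0481826768], atol=1e-6)
        assert est.loglik_ == pytest.approx(36.43019438, abs=1e-5)

    def test_fixed_lambda_regression(self, oracle_cov, oracle_traits):
        est = hf.PGLSRegression(cov=oracle_cov, lam=0.5).fit(
            oracle_traits[["x"]], oracle_traits["y"])
        np.testing.assert_allclose(
            est.beta_, [0.1049461556, 0.4237680309], atol=1e-8)
        assert est.loglik_ == pytest.approx(35.75514000, abs=1e-6)

    def test_single_trait_signal(self, oracle_cov, oracle_traits):
        sig = hf.phylo_signal(oracle_traits["y"], oracle_cov)
        assert sig.lambda_hat == pytest.approx(0.39411804, abs=2e-5)
        assert sig.loglik == pytest.approx(20.91916095, abs=1e-5)
        assert sig.loglik0 == pytest.approx(19.34741442, abs=1e-5)
        assert sig.p_lrt == pytest.approx(0.07623039, abs=1e-5)

    def test_signal_absent_trait(self, oracle_cov, oracle_traits):
        sig = hf.phylo_signal(oracle_traits["x"], oracle_cov)
        assert sig.lambda_hat == pytest.approx(0.0, abs=1e-3)
        assert sig.p_lrt == pytest.approx(1.0, abs=1e-3)


class TestLambdaRecovery:
    def test_moderate_scale_beta_and_lambda_recovery(self):
        """β̂ and λ̂ recover the generator on a 150-tip tree (40 replicates)."""
        tree = hf.sim_tree(150, seed=40)
        cov = hf.phylo_cov(tree)
        n = 150
        rng = np.random.default_rng(41)
        L = np.linalg.cholesky(cov.with_lambda(0.5) + 1e-12 * np.eye(n))
        betas, lams = [], []
        for _ in range(40):
            x = rng.uniform(0, 1, n)
            y = 0.2 + 0.4 * x + 0.15 * (L @ rng.standard_normal(n))
            est = hf.PGLSRegression(cov=cov).fit(x, y)
            betas.append(est.beta_)
            lams.append(est.lambda_)
        mean_beta = np.mean(betas, axis=0)
        mc_se = np.std(betas, axis=0, ddof=1) / np.sqrt(40)
        assert abs(mean_beta[0] - 0.2) < 3 * mc_se[0] + 1e-3
        assert abs(mean_beta[1] - 0.4) < 3 * mc_se[1] + 1e-3
        assert abs(np.mean(lams) - 0.5) < 0.1

    def test_likelihood_at_optimum_dominates_endpoints(
            self, oracle_cov, oracle_traits):
        y = oracle_traits["y"].to_numpy()
        x = oracle_traits["x"].to_numpy()
        est = hf.PGLSRegression(cov=oracle_cov).fit(x, y)
        gls = _ProfileGLS(oracle_cov,
                          np.column_stack([np.ones(20), x]), y)
        assert est.loglik_ >= gls.loglik(0.0) - 1e-9
        assert est.loglik_ >= gls.loglik(min(1.0, oracle_cov.lambda_max * 0.99)) - 1e-9

    def test_lambda_ci_brackets_estimate(self, oracle_cov, oracle_traits):
        est = hf.PGLSRegression(cov=oracle_cov).fit(
            oracle_traits[["x"]], oracle_traits["y"])
        lo, hi = est.lambda_ci_
        assert lo <= est.lambda_ <= hi

    def test_whitened_residuals_centred_and_orthogonal(self):
        tree = hf.sim_tree(100, seed=42)
        cov = hf.phylo_cov(tree)
        rng = np.random.default_rng(43)
        L = np.linalg.cholesky(cov.with_lambda(0.7) + 1e-12 * np.eye(100))
        x = rng.uniform(0, 1, 100)
        y = 0.1 + 0.5 * x + 0.1 * (L @ rng.standard_normal(100))
        est = hf.PGLSRegression(cov=cov).fit(x, y)
        V = cov.with_lambda(est.lambda_)
        Vi = np.linalg.inv(V)
        Xd = np.column_stack([np.ones(100), x])
        e = y - Xd @ est.beta_
        # GLS normal equations: design ⟂ residuals in the V metric
        np.testing.assert_allclose(Xd.T @ Vi @ e, 0.0, atol=1e-8)
        z = np.linalg.solve(np.linalg.cholesky(V), e)
        assert abs(z.mean()) < 3 * z.std(ddof=1) / np.sqrt(100)


class TestModelSpecAndSelection:
    def test_design_forms(self):
        X = pd.DataFrame({"cc": [0.1, 0.2, 0.4]})
        lin = ModelSpec("gc", "linear", ("cc",)).design(X)
        assert list(lin.columns) == ["cc"]
        quad = ModelSpec("gc", "quadratic", ("cc",)).design(X)
        assert list(quad.columns) == ["cc^2", "cc"]
        np.testing.assert_allclose(quad["cc^2"], X["cc"] ** 2)
        logd = ModelSpec("gc", "log", ("cc",)).design(X)
        np.testing.assert_allclose(logd["log(cc)"], np.log(X["cc"]))

    def test_log_of_nonpositive_predictor_is_an_error(self):
        X = pd.DataFrame({"cc": [0.0, 0.2]})
        with pytest.raises(ValueError, match="positive"):
            ModelSpec("gc", "log", ("cc",)).design(X)

    def test_identical_fits_tie_breaks_to_first(self, oracle_cov, oracle_traits):
        spec = ModelSpec("y", "linear", ("x",))
        f1 = hf.pgls_fit(oracle_traits["y"], spec, oracle_traits, oracle_cov)
        f2 = hf.pgls_fit(oracle_traits["y"], spec, oracle_traits, oracle_cov)
        best, table = hf.compare_models({"first": f1, "second": f2})
        assert table["delta_aic"].max() == pytest.approx(0.0, abs=1e-9)
        assert table.loc[table["selected"], "model"].iloc[0] == "first"

    def test_strong_quadratic_generator_selected(self):
        tree = hf.sim_tree(120, seed=50)
        cov = hf.phylo_cov(tree)
        rng = np.random.default_rng(51)
        L = np.linalg.cholesky(cov.with_lambda(0.5) + 1e-12 * np.eye(120))
        x = rng.uniform(0.05, 0.65, 120)
        y = 0.1 + 0.9 * x**2 - 0.25 * x + 0.03 * (L @ rng.standard_normal(120))
        X = pd.DataFrame({"cc": x}, index=cov.taxa)
        ys = pd.Series(y, index=cov.taxa)
        fits = [hf.pgls_fit(ys, ModelSpec("gc", f, ("cc",)), X, cov)
                for f in ("linear", "quadratic", "log")]
        best, _ = hf.compare_models(fits)
        assert best.model.form == "quadratic"

    def test_nested_model_never_beats_wider_by_more_than_two(self):
        """2k−2lnL with nested ML fits: AIC_nested ≤ AIC_wider + 2 is
        impossible to violate from the nested side; check the sampled fits."""
        tree = hf.sim_tree(80, seed=52)
        cov = hf.phylo_cov(tree)
        rng = np.random.default_rng(53)
        L = np.linalg.cholesky(cov.with_lambda(0.5) + 1e-12 * np.eye(80))
        x = rng.uniform(0.05, 0.65, 80)
        y = 0.1 + 0.8 * x**2 - 0.2 * x + 0.05 * (L @ rng.standard_normal(80))
        X = pd.DataFrame({"cc": x}, index=cov.taxa)
        ys = pd.Series(y, index=cov.taxa)
        lin = hf.pgls_fit(ys, ModelSpec("gc", "linear", ("cc",)), X, cov)
        quad = hf.pgls_fit(ys, ModelSpec("gc", "quadratic", ("cc",)), X, cov)
        assert lin.aic - quad.aic > -2.0 - 1e-9

    def test_differing_sample_sizes_rejected(self, oracle_cov, oracle_traits):
        spec = ModelSpec("y", "linear", ("x",))
        full = hf.pgls_fit(oracle_traits["y"], spec, oracle_traits, oracle_cov)
        part = hf.pgls_fit(oracle_traits["y"].iloc[:15], spec,
                           oracle_traits.iloc[:15], oracle_cov)
        with pytest.raises(ModelComparisonError):
            hf.compare_models([full, part])


class TestGuards:
    def test_singular_design_rejected(self, oracle_cov, oracle_traits):
        X = np.column_stack([oracle_traits["x"], oracle_traits["x"]])
        with pytest.raises(np.linalg.LinAlgError):
            hf.PGLSRegression(cov=oracle_cov).fit(X, oracle_traits["y"])

    def test_constant_trait_rejected(self, oracle_cov):
        y = pd.Series(0.5, index=oracle_cov.taxa)
        with pytest.raises(ValueError, match="constant"):
            hf.phylo_signal(y, oracle_cov)

    def test_aic_counts_sigma_and_lambda(self, oracle_cov, oracle_traits):
        est = hf.PGLSRegression(cov=oracle_cov).fit(
            oracle_traits[["x"]], oracle_traits["y"])
        assert est.aic_ == pytest.approx(2 * 4 - 2 * est.loglik_)
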