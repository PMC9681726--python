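import math

import numpy as np
import pytest
from scipy import special

import larimorph as lm
from larimorph.phylo_beta import beta_loglik, quantile_residuals


class TestSqueeze:
    def test_boundary_values(self):
        assert lm.squeeze(0.0) == pytest.approx(1e-4)
        assert lm.squeeze(1.0) == pytest.approx(0.9999)
        assert lm.squeeze(0.84) == 0.84

    def test_vectorized(self):
        out = lm.squeeze(np.array([0.0, 0.5, 1.0]))
        np.testing.assert_allclose(out, [1e-4, 0.5, 0.9999])

    def test_domain(self):
        with pytest.raises(ValueError):
            lm.squeeze(1.2)
        with pytest.raises(ValueError):
            lm.squeeze(-0.1)


class TestRatiosAndPredictions:
    def test_exponentiated_coefficients(self):
        # exp of a coefficient printed at 2 dp carries a rounding band of
        # about exp(b)*0.005 ~ 0.03 at the intercept
        assert lm.coef_to_ratio(1.65) == pytest.approx(5.20, abs=0.03)
        assert round(lm.coef_to_ratio(0.34), 2) == 1.40
        assert round(lm.coef_to_ratio(-0.05), 2) == 0.95
        assert lm.coef_to_ratio(0.0) == 1.0

    def test_baseline_proportions(self):
        """Inverse-logit predictions at the equator for 0/1/2 SD of wing loading."""
        coefs = (1.65, 0.34, -0.05)
        assert round(lm.predict_proportion(coefs, 0.0, 0.0), 2) == 0.84
        assert round(lm.predict_proportion(coefs, 1.0, 0.0), 2) == 0.88
        assert round(lm.predict_proportion(coefs, 2.0, 0.0), 2) == 0.91

    def test_ratio_and_prediction_consistency(self):
        """r/(1+r) at the intercept ratio equals the baseline prediction."""
        r = lm.coef_to_ratio(1.65)
        assert r / (1.0 + r) == pytest.approx(lm.predict_proportion((1.65, 0.34, -0.05), 0, 0))

    def test_logit_inverse_identity(self):
        coefs = (1.65, 0.34, -0.05)
        for wl, lat in [(0.3, 12.0), (-1.2, 55.0), (2.0, 0.0)]:
            p = lm.predict_proportion(coefs, wl, lat)
            eta = coefs[0] + coefs[1] * wl + coefs[2] * lat
            assert special.logit(p) == pytest.approx(eta, abs=1e-10)

    def test_monotonicity_in_positive_coefficient(self):
        coefs = (1.65, 0.34, -0.05)
        p = [lm.predict_proportion(coefs, wl, 10.0) for wl in np.linspace(-2, 2, 9)]
        assert np.all(np.diff(p) > 0)


@pytest.fixture(scope="module")
def beta_setup():
    tree = lm.simulate_tree(49, 0.21, seed=5)
    n = 49
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         np.abs(rng.uniform(-70, 70, size=n))])
    C = tree.correlation_matrix()
    return tree, X, C


@pytest.fixture(scope="module")
def fitted_beta(beta_setup):
    tree, X, C = beta_setup
    y = lm.simulate_beta_traits(
        tree, X, {"beta": (1.65, 0.34, -0.05), "phi": 30.0, "sigma2_phylo": 0.5}, seed=2
    )
    y = lm.squeeze(np.where(y < 1e-4, 0.0, np.where(y > 0.9999, 1.0, y)))
    return lm.fit_phylo_beta(X, y, C), y


class TestFit:
    def test_plain_beta_matches_independent_ml(self, beta_setup):
        """sigma2_p = 0 reduces to plain beta regression; cross-check against
        an independently implemented maximum-likelihood fit."""
        from statsmodels.othermod.betareg import BetaModel

        tree, X, C = beta_setup
        y = lm.simulate_beta_traits(
            tree, X, {"beta": (1.65, 0.34, -0.05), "phi": 30.0, "sigma2_phylo": 0.0},
            seed=9,
        )
        y = lm.squeeze(y)
        ours = lm.fit_phylo_beta(X, y, C, fix_sigma2=0.0)
        sm = BetaModel(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.beta, sm.params[:3], atol=1e-4)
        assert ours.phi == pytest.approx(math.exp(sm.params[3]), rel=1e-4)
        assert ours.loglik == pytest.approx(sm.llf, abs=1e-6)

    def test_laplace_at_zero_variance_is_exact(self, beta_setup, fitted_beta):
        """The marginal loglik at sigma2_p = 0 equals the plain beta loglik."""
        from larimorph.phylo_beta import _laplace_loglik

        tree, X, C = beta_setup
        fit, y = fitted_beta
        Cinv = np.linalg.inv(C)
        logdetC = float(np.linalg.slogdet(C)[1])
        theta = np.concatenate([fit.beta, [math.log(fit.phi), 0.0]])
        lap = _laplace_loglik(theta, X, y, Cinv, logdetC, len(y))
        plain = beta_loglik(X @ fit.beta, y, fit.phi)
        assert lap == plain

    def test_fit_recovers_generating_coefficients(self, fitted_beta):
        fit, _ = fitted_beta
        assert fit.converged
        for b, truth, se in zip(fit.beta, (1.65, 0.34, -0.05), fit.se):
            assert abs(b - truth) < 4 * se  # single replicate sanity band
        assert fit.phi > 0
        assert fit.sigma2_phylo >= 0

    def test_degenerate_constant_response(self):
        n = 20
        X = np.ones((n, 1))
        y = np.full(n, 0.7)
        C = np.eye(n)
        fit = lm.fit_phylo_beta(X, y, C)
        assert fit.beta[0] == pytest.approx(special.logit(0.7), abs=1e-2)
        assert fit.phi > 1e3  # precision grows until the likelihood flattens
        assert fit.sigma2_phylo == pytest.approx(0.0, abs=1e-4)

    def test_unsqueezed_input_rejected(self, beta_setup):
        tree, X, C = beta_setup
        y = np.linspace(0, 1, 49)
        with pytest.raises(ValueError):
            lm.fit_phylo_beta(X, y, C)


class TestQuantileResiduals:
    def test_self_consistency_uniformity(self, beta_setup):
        """Residuals of data simulated from the fitted model are uniform:
        KS p > 0.01 in at least 95% of seeded runs.

        Checked on a fit without the phylogenetic random effect, where the
        per-observation quantiles are independent and the pooled KS test has
        its nominal distribution.  A shared correlated random-effect draw
        clusters the quantiles and makes the pooled KS anti-conservative
        (see the marginal-uniformity test below), exactly as for
        unconditional simulation-based residuals in mixed models generally.
        """
        tree, X, C = beta_setup
        y0 = lm.simulate_beta_traits(
            tree, X, {"beta": (1.65, 0.34, -0.05), "phi": 30.0, "sigma2_phylo": 0.0},
            seed=77,
        )
        fit = lm.fit_phylo_beta(X, lm.squeeze(y0), C, fix_sigma2=0.0)
        params = {"beta": fit.beta, "phi": fit.phi, "sigma2_phylo": 0.0}
        ok = 0
        runs = 100
        for r in range(runs):
            y_new = lm.squeeze(lm.simulate_beta_traits(tree, X, params, seed=3000 + r))
            res = quantile_residuals(fit, y=y_new, n_sim=250, seed=r)
            ok += res.ks_p_value > 0.01
        assert ok >= 95

    def test_marginal_uniformity_under_correlated_effects(self, beta_setup, fitted_beta):
        """With a phylogenetic random effect the quantiles stay marginally
        uniform (mean 1/2, variance 1/12) even though each run's pooled KS
        test is anti-conservative due to the shared correlated draw."""
        tree, X, C = beta_setup
        fit, _ = fitted_beta
        params = {"beta": fit.beta, "phi": fit.phi, "sigma2_phylo": fit.sigma2_phylo}
        pooled = []
        for r in range(60):
            y_new = lm.squeeze(lm.simulate_beta_traits(tree, X, params, seed=6000 + r))
            pooled.append(quantile_residuals(fit, y=y_new, n_sim=250, seed=r).quantiles)
        q = np.concatenate(pooled)
        assert np.mean(q) == pytest.approx(0.5, abs=0.03)
        assert np.var(q) == pytest.approx(1.0 / 12.0, rel=0.15)

    def test_shifted_data_concentrates_near_one(self, fitted_beta):
        fit, y = fitted_beta
        y_shift = np.clip(y + 0.3, None, 0.9999)
        res = quantile_residuals(fit, y=y_shift, n_sim=250, seed=0)
        assert np.median(res.quantiles) > 0.8
        assert res.ks_p_value < 0.01

    def test_quantiles_in_open_unit_interval(self, fitted_beta):
        fit, y = fitted_beta
        res = quantile_residuals(fit, n_sim=250, seed=1)
        assert np.all(res.quantiles > 0.0)
        assert np.all(res.quantiles < 1.0)

    def test_small_nsim_warns(self, fitted_beta):
        fit, _ = fitted_beta
        with pytest.warns(UserWarning):
            quantile_residuals(fit, n_sim=50, seed=0)
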