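import math

import numpy as np
import pytest
from scipy import optimize, stats

import larimorph as lm
from larimorph.pgls import gls_fit


def _random_instance(seed, n=12, p=3):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
    y = rng.normal(size=n)
    return X, y


class TestGLSCore:
    @pytest.mark.parametrize("seed", range(10))
    def test_identity_equals_ols(self, seed):
        X, y = _random_instance(seed)
        res = gls_fit(X, y, np.eye(len(y)))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.beta, beta_ols, atol=1e-10)

    def test_perfect_fit_flagged(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        y = X @ np.array([1.0, 2.0])
        res = gls_fit(X, y, np.eye(5))
        assert res.degenerate
        np.testing.assert_allclose(res.beta, [1.0, 2.0], atol=1e-10)
        assert res.sigma2 == pytest.approx(0.0, abs=1e-20)
        assert math.isinf(res.loglik)

    def test_rank_deficiency_rejected(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError):
            gls_fit(X, np.arange(6.0), np.eye(6))

    def test_matches_bruteforce_mvn_ml(self):
        """4-point GLS equals numeric maximization of the MVN likelihood."""
        rng = np.random.default_rng(7)
        A = rng.normal(size=(4, 4))
        C0 = A @ A.T + 4 * np.eye(4)
        X = np.column_stack([np.ones(4), rng.normal(size=4)])
        y = rng.normal(size=4)
        res = gls_fit(X, y, C0)

        sign, logdetC = np.linalg.slogdet(C0)
        Cinv = np.linalg.inv(C0)

        def nll(t):
            beta, ls2 = t[:2], t[2]
            r = y - X @ beta
            s2 = math.exp(ls2)
            return 0.5 * (4 * math.log(2 * math.pi) + 4 * ls2 + logdetC
                          + r @ Cinv @ r / s2)

        opt = optimize.minimize(nll, [0.0, 0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
        np.testing.assert_allclose(res.beta, opt.x[:2], atol=1e-6)
        assert res.sigma2 == pytest.approx(math.exp(opt.x[2]), abs=1e-6)
        assert res.loglik == pytest.approx(-opt.fun, abs=1e-6)


class TestModelFitting:
    def test_lambda_endpoints_match_np_and_bm(self, mantle_design):
        tree, y, X = mantle_design
        np_fit = lm.fit_model(tree, y, X, "NP")
        bm_fit = lm.fit_model(tree, y, X, "BM")
        C = tree.mrca_depth_matrix()
        at0 = gls_fit(X, y, lm.lambda_transform(C, 0.0))
        at1 = gls_fit(X, y, lm.lambda_transform(C, 1.0))
        np.testing.assert_allclose(at0.beta, np_fit.beta, atol=1e-8)
        assert at0.loglik == pytest.approx(np_fit.loglik, abs=1e-8)
        np.testing.assert_allclose(at1.beta, bm_fit.beta, atol=1e-8)
        assert at1.loglik == pytest.approx(bm_fit.loglik, abs=1e-8)

    def test_lambda_dominates_bm_by_nesting(self, mantle_design):
        tree, y, X = mantle_design
        bm = lm.fit_model(tree, y, X, "BM")
        lam = lm.fit_model(tree, y, X, "LAMBDA")
        assert lam.loglik >= bm.loglik - 1e-8

    def test_large_alpha_reproduces_np(self, mantle_design):
        tree, y, X = mantle_design
        np_fit = lm.fit_model(tree, y, X, "NP")
        big = gls_fit(X, y, lm.ou_cov(tree, alpha=1e3 / tree.height()))
        np.testing.assert_allclose(big.beta, np_fit.beta, atol=1e-4)

    def test_ou_optimum_beats_grid(self, mantle_design):
        """The profiled optimum is at least the best of a fine grid."""
        tree, y, X = mantle_design
        fit = lm.fit_model(tree, y, X, "OU")
        h = tree.height()
        grid = np.geomspace(1e-6 / h, 1e3 / h, 100)
        vals = [gls_fit(X, y, lm.ou_cov(tree, a)).loglik for a in grid]
        assert fit.loglik >= max(vals) - 1e-6

    def test_aic_consistent(self, mantle_design):
        tree, y, X = mantle_design
        for m, k in (("NP", 4), ("BM", 4), ("OU", 5), ("LAMBDA", 5)):
            fit = lm.fit_model(tree, y, X, m)
            assert fit.k == k
            assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)


class TestLRT:
    def test_reported_loglik_pairs(self):
        """Chi-square LRT p-values from the published log-likelihoods."""
        ou_vs_np = 2.0 * (-125.15 - (-128.21))
        assert ou_vs_np == pytest.approx(6.12)
        assert stats.chi2.sf(ou_vs_np, 1) == pytest.approx(0.013, abs=5e-4)
        lam_vs_np = 2.0 * (-127.09 - (-128.21))
        assert stats.chi2.sf(lam_vs_np, 1) == pytest.approx(0.134, abs=5e-4)

    def test_lrt_object(self, mantle_design):
        tree, y, X = mantle_design
        np_fit = lm.fit_model(tree, y, X, "NP")
        ou_fit = lm.fit_model(tree, y, X, "OU")
        res = lm.lrt(np_fit, ou_fit)
        assert res.statistic >= 0
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1))

    def test_equal_logliks_give_p_one(self, mantle_design):
        tree, y, X = mantle_design
        fit = lm.fit_model(tree, y, X, "NP")
        import copy

        general = copy.copy(fit)
        general.k = fit.k + 1
        res = lm.lrt(fit, general)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_type_i_error_near_nominal(self, gull_tree):
        """LRT of lambda vs NP under NP data: size in [0.02, 0.09] at nominal 0.05.

        The boundary at lambda = 0 makes the plain chi-square test
        conservative, so the band sits mostly below 0.05.
        """
        tree = gull_tree
        n = tree.n_tips
        rng = np.random.default_rng(2024)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        rejections = 0
        reps = 500
        for r in range(reps):
            y = rng.normal(size=n)
            np_fit = lm.fit_model(tree, y, X, "NP")
            lam_fit = lm.fit_model(tree, y, X, "LAMBDA")
            if lm.lrt(np_fit, lam_fit).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09


class TestHalfLife:
    def test_values(self):
        assert lm.half_life(math.log(2.0)) == pytest.approx(1.0)
        assert lm.half_life(27.13) == pytest.approx(0.026, abs=5e-4)
        assert lm.half_life(1e9) == pytest.approx(0.0, abs=1e-8)
        with pytest.raises(ValueError):
            lm.half_life(0.0)


class TestLambdaCI:
    def test_strong_signal_excludes_zero(self, gull_tree):
        tree = gull_tree
        n = tree.n_tips
        X = np.ones((n, 1))
        y = lm.simulate_traits(tree, X, "BM", {"beta": [5.0], "sigma2": 40.0}, seed=3)
        fit = lm.fit_model(tree, y, X, "LAMBDA")
        lo, hi = fit.param_ci
        assert lo > 0.0
        assert lo <= fit.param <= hi

    def test_interior_endpoints_sit_at_drop(self, mantle_design):
        tree, y, X = mantle_design
        fit = lm.fit_model(tree, y, X, "LAMBDA")
        lo, hi = lm.lambda_profile_ci(fit)
        assert lo <= fit.param <= hi
        lmax = fit._profile(fit.param)
        drop = stats.chi2.ppf(0.95, 1) / 2.0
        for end in (lo, hi):
            if 0.0 < end < 1.0:
                assert lmax - fit._profile(end) == pytest.approx(drop, abs=0.01)


class TestOLSAndCorrelation:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = lm.ols_fit(x, 2.0 * x + 1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.r2 == pytest.approx(1.0)

    def test_flat_hand_case(self):
        res = lm.ols_fit([0.0, 1.0, 2.0], [0.0, 1.0, 0.0])
        assert res.slope == pytest.approx(0.0)
        assert res.r2 == pytest.approx(0.0)

    def test_pearson_limits(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert lm.pearson(x, -x) == pytest.approx(-1.0)
        assert lm.pearson(x, 3 * x + 2) == pytest.approx(1.0)


def test_parameter_recovery_bias(gull_tree):
    """Mean signed bias of the wing-loading effect under OU generation is small."""
    tree = gull_tree
    n = tree.n_tips
    rng = np.random.default_rng(55)
    X = np.column_stack([np.ones(n), rng.normal(size=n),
                         np.abs(rng.uniform(-70, 70, size=n))])
    truth = {"beta": (10.4, 1.2, -0.07), "alpha": 27.13, "sigma2": 595.77}
    bias = []
    for r in range(200):
        y = lm.simulate_traits(tree, X, "OU", truth, seed=9000 + r)
        fit = lm.fit_model(tree, y, X, "OU")
        bias.append(fit.beta[1] - 1.2)
    assert abs(np.mean(bias)) <= 0.15
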