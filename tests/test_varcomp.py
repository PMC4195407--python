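import numpy as np
import pytest

from rhm import (VarCompModel, blup_effects, compute_grm, fit_bivariate,
                 fit_reml, loglik_restricted)
from conftest import naive_restricted_loglik


def toy_model(n=10, seed=42, ratio=1.0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((n, n))
    K = A @ A.T / n
    L = np.linalg.cholesky(K + 1e-9 * np.eye(n))
    y = np.sqrt(ratio) * (L @ rng.standard_normal(n)) + rng.standard_normal(n)
    return VarCompModel(y, [("g", K)]), K


class TestLoglikRestricted:
    def test_matches_naive_dense_formula(self):
        model, K = toy_model(n=15, seed=1)
        for theta in ([0.5, 1.0], [2.0, 0.3], [1e-3, 1.2]):
            got = loglik_restricted(model, theta)
            want = naive_restricted_loglik(model.y, model.X, [K], np.array(theta))
            assert got == pytest.approx(want, abs=1e-8)

    def test_residual_only_limit(self):
        model, K = toy_model(n=12, seed=2)
        null = VarCompModel(model.y, [])
        fit0 = fit_reml(null)
        # adding a component at (numerical) zero variance changes nothing
        ll = loglik_restricted(model, [1e-300, fit0.sigma2_e])
        assert ll == pytest.approx(fit0.loglik, abs=1e-6)

    def test_optimum_is_local_max(self):
        model, _ = toy_model(n=12, seed=3)
        fit = fit_reml(model)
        opt = np.array([fit.sigma2[0], fit.sigma2_e])
        ll_opt = loglik_restricted(model, opt)
        for bump in ([1.05, 1.0], [0.95, 1.0], [1.0, 1.05], [1.0, 0.95]):
            assert ll_opt >= loglik_restricted(model, opt * bump) - 1e-9


class TestFitReml:
    def test_residual_only_closed_form(self):
        rng = np.random.default_rng(4)
        y = rng.standard_normal(25) * 2 + 3
        fit = fit_reml(VarCompModel(y, []))
        assert fit.sigma2_e == pytest.approx(np.var(y, ddof=1), rel=1e-12)
        assert fit.loglik == pytest.approx(
            naive_restricted_loglik(y, np.ones((25, 1)), [],
                                    np.array([np.var(y, ddof=1)])), abs=1e-9)

    def test_eigen_and_dense_paths_agree(self):
        # single component uses the rotated fast path; forcing two identical
        # half-weight copies goes dense and must reach the same optimum
        model, K = toy_model(n=30, seed=5)
        fit1 = fit_reml(model)
        dense = VarCompModel(model.y, [("a", 0.5 * K), ("b", 0.5 * K)])
        fit2 = fit_reml(dense)
        assert fit2.loglik == pytest.approx(fit1.loglik, abs=1e-5)
        assert fit2.sigma2.sum() / 2 == pytest.approx(fit1.sigma2[0], rel=2e-2)

    def test_boundary_null_component_pins_to_floor(self):
        # with no genetic signal the variance estimate sits at the floor in
        # about half of replicates (boundary half-chi-square mass)
        rng = np.random.default_rng(6)
        n, hits = 80, 0
        reps = 30
        for _ in range(reps):
            A = rng.standard_normal((n, n))
            K = A @ A.T / n
            y = rng.standard_normal(n)
            fit = fit_reml(VarCompModel(y, [("g", K)]))
            vy = np.var(y, ddof=1)
            if fit.sigma2[0] <= 2e-8 * vy:
                hits += 1
        assert hits >= 0.35 * reps

    def test_scale_equivariance(self):
        model, K = toy_model(n=40, seed=7)
        fit = fit_reml(model)
        c = 3.7
        fit_c = fit_reml(VarCompModel(c * model.y, [("g", K)]))
        assert fit_c.sigma2[0] == pytest.approx(c ** 2 * fit.sigma2[0], rel=1e-4)
        assert fit_c.sigma2_e == pytest.approx(c ** 2 * fit.sigma2_e, rel=1e-4)
        assert fit_c.h2["g"] == pytest.approx(fit.h2["g"], abs=1e-6)

    def test_h2_fractions_sum_to_one(self):
        model, _ = toy_model(n=30, seed=8)
        fit = fit_reml(model)
        assert sum(fit.h2.values()) + fit.residual_fraction == pytest.approx(1.0, abs=1e-8)

    def test_constant_y_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_reml(VarCompModel(np.ones(10), []))

    def test_lrt_nonnegative_for_nested_fits(self, small_dataset):
        gm = small_dataset["genotypes"]
        y = small_dataset["phenotypes"].trait("trait1").to_numpy()
        G = compute_grm(gm).values
        Q = compute_grm(gm, snp_subset=np.arange(40)).values
        ll0 = fit_reml(VarCompModel(y, [("bg", G)])).loglik
        llf = fit_reml(VarCompModel(y, [("region", Q), ("bg", G)])).loglik
        assert 2 * (llf - ll0) >= -1e-6


class TestBlup:
    def test_zero_variance_component_gives_zero_blups(self):
        model, _ = toy_model(n=20, seed=9)
        fit = fit_reml(model)
        fit.sigma2[0] = 0.0  # force the boundary case
        with pytest.warns(RuntimeWarning, match="boundary"):
            ebv = blup_effects(fit, "g")
        assert np.all(ebv.values == 0)

    def test_matches_naive_dense_evaluation(self):
        rng = np.random.default_rng(10)
        n = 18
        A = rng.standard_normal((n, n))
        K1 = A @ A.T / n
        B = rng.standard_normal((n, n))
        K2 = B @ B.T / n
        L = np.linalg.cholesky(K1 + 1e-9 * np.eye(n))
        y = L @ rng.standard_normal(n) + rng.standard_normal(n)
        model = VarCompModel(y, [("a", K1), ("b", K2)])
        fit = fit_reml(model)
        # naive: u_hat = s2 K V^-1 (y - X beta)
        V = fit.sigma2[0] * K1 + fit.sigma2[1] * K2 + fit.sigma2_e * np.eye(n)
        Vi = np.linalg.inv(V)
        X = model.X
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u_naive = fit.sigma2[0] * K1 @ Vi @ (y - X @ beta)
        if fit.sigma2[0] > 1e-6:
            ebv = blup_effects(fit, "a")
            np.testing.assert_allclose(ebv.values, u_naive, atol=1e-8)

    def test_eigen_path_blups_match_dense(self):
        model, K = toy_model(n=25, seed=12, ratio=2.0)
        fit = fit_reml(model)
        V = fit.sigma2[0] * K + fit.sigma2_e * np.eye(25)
        Vi = np.linalg.inv(V)
        X = model.X
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ model.y)
        u_naive = fit.sigma2[0] * K @ Vi @ (model.y - X @ beta)
        np.testing.assert_allclose(blup_effects(fit, "g").values, u_naive,
                                   atol=1e-7)


class TestBivariate:
    def test_duplicate_trait_hits_plus_one_boundary(self):
        model, K = toy_model(n=60, seed=13, ratio=1.5)
        G = K + 1e-6 * np.eye(60)
        fit = fit_bivariate(model.y, model.y.copy(), G)
        assert fit.rg > 0.97

    def test_grid_oracle_small_instance(self):
        # the bivariate optimum must dominate a coarse grid of the same
        # restricted likelihood evaluated through the dense machinery
        rng = np.random.default_rng(14)
        n = 30
        A = rng.standard_normal((n, n))
        G = A @ A.T / n
        L = np.linalg.cholesky(G + 1e-9 * np.eye(n))
        g1 = L @ rng.standard_normal(n)
        g2 = 0.8 * g1 + 0.6 * (L @ rng.standard_normal(n))
        y1 = g1 + rng.standard_normal(n)
        y2 = g2 + rng.standard_normal(n)
        fit = fit_bivariate(y1, y2, G)
        # dense 2n x 2n evaluation of the same model at the optimum
        theta = [fit.var_g[0, 0], fit.var_g[0, 1], fit.var_g[1, 1],
                 fit.var_e[0, 0], fit.var_e[0, 1], fit.var_e[1, 1]]
        ll_dense = _dense_bivariate_loglik(y1, y2, G, theta)
        assert fit.loglik == pytest.approx(ll_dense, abs=1e-6)
        for scale in (0.9, 1.1):
            pert = list(theta)
            pert[0] *= scale
            assert ll_dense >= _dense_bivariate_loglik(y1, y2, G, pert) - 1e-8


def _dense_bivariate_loglik(y1, y2, G, theta):
    """Naive stacked evaluation (independent of the block-diagonal fast path)."""
    n = y1.size
    g11, g12, g22, e11, e12, e22 = theta
    Sg = np.array([[g11, g12], [g12, g22]])
    Se = np.array([[e11, e12], [e12, e22]])
    V = np.kron(Sg, G) + np.kron(Se, np.eye(n))
    X = np.kron(np.eye(2), np.ones((n, 1)))
    y = np.concatenate([y1, y2])
    return _raw(y, X, V)


def _raw(y, X, V):
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    s1, ldV = np.linalg.slogdet(V)
    s2, ldX = np.linalg.slogdet(XtViX)
    return -0.5 * (ldV + ldX + float(r @ Vi @ r) + (n - p) * np.log(2 * np.pi))
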