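"""Quadratic-inference-function (frequentist GMM) tests."""

import numpy as np
import pytest

import pseudogmm as pg
from pseudogmm.gmm import _fit_qif, basis_set, moment_state

from conftest import random_censored_sample


class TestBasisSet:
    def test_exch_k3(self):
        b = basis_set("exch", 3)
        np.testing.assert_array_equal(b.matrices[0], np.eye(3))
        np.testing.assert_array_equal(
            b.matrices[1], [[0, 1, 1], [1, 0, 1], [1, 1, 0]]
        )

    def test_ar1_k3(self):
        b = basis_set("ar1", 3)
        np.testing.assert_array_equal(
            b.matrices[1], [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        )

    def test_ind_any_k(self):
        assert basis_set("ind", 7).J == 1

    def test_invalid(self):
        with pytest.raises(ValueError):
            basis_set("toeplitz", 3)
        with pytest.raises(ValueError):
            basis_set("exch", 1)


class TestMomentState:
    def test_dimensions(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        ms = moment_state(np.zeros(design.L), pseudo, design, basis_set("exch", 5))
        assert ms.U.shape == (12,)
        assert ms.C.shape == (12, 12)

    def test_brute_force_c_on_toy(self):
        rng = np.random.default_rng(0)
        s = random_censored_sample(rng, 5, censor_frac=0.2)
        K = min(2, np.unique(s.time[s.status == 1]).size)
        grid = pg.select_time_grid(s, K)
        po = pg.pseudo_obs_matrix(s, grid)
        d = pg.build_design(s, grid)
        basis = basis_set("exch", grid.K) if grid.K >= 2 else basis_set("ind", grid.K)
        beta = rng.normal(scale=0.3, size=d.L)
        ms = moment_state(beta, po, d, basis)
        mu, D = pg.mean_and_jacobian(beta, d)
        u = []
        for i in range(d.n):
            r = po.values[i] - mu[i]
            u.append(np.concatenate([D[i].T @ (M @ r) for M in basis.matrices]))
        u = np.array(u)
        np.testing.assert_allclose(ms.U, u.mean(axis=0), atol=1e-12)
        C = sum(np.outer(ui, ui) for ui in u) / d.n**2
        np.testing.assert_allclose(ms.C, C, atol=1e-12)

    def test_u_vanishes_at_gee_ind_solution(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        gee = pg.PseudoGEE(pseudo, design).fit()
        ms = moment_state(gee.params, pseudo, design, basis_set("ind", 5))
        assert np.max(np.abs(ms.U)) < 1e-7


class TestQIF:
    def test_nonnegative_on_random_draws(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        basis = basis_set("exch", 5)
        rng = np.random.default_rng(9)
        start = pg.starting_values(pseudo, design)
        for _ in range(100):
            beta = start + rng.normal(scale=0.1, size=design.L)
            q = pg.qif(beta, pseudo, design, basis)
            assert q >= 0.0

    def test_zero_at_ind_solution(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        res = pg.PseudoGMM(pseudo, design, basis="ind").fit()
        assert res.objective < 1e-10

    def test_infinite_outside_support(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        beta = np.zeros(design.L)
        beta[0] = 25.0  # saturated means, degenerate scores
        assert pg.qif(beta, pseudo, design, basis_set("exch", 5)) == np.inf


class TestFitGMM:
    def test_ind_equals_gee(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        gee = pg.PseudoGEE(pseudo, design).fit()
        gmm = pg.PseudoGMM(pseudo, design, basis="ind").fit()
        np.testing.assert_allclose(gmm.params, gee.params, atol=1e-6)
        # sandwich covariances agree too under independence (the analytic
        # dU/dbeta differs from Gamma0 only by a second-order residual term)
        np.testing.assert_allclose(gmm.bse, gee.bse, rtol=0.02)

    def test_descent_from_start(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        model = pg.PseudoGMM(pseudo, design, basis="exch")
        start = pg.starting_values(pseudo, design)
        res = model.fit(start=start)
        assert res.objective <= model.qif(start) + 1e-12

    def test_covariance_symmetric_psd(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        for kind in ("ind", "exch", "ar1"):
            res = pg.PseudoGMM(pseudo, design, basis=kind).fit()
            np.testing.assert_allclose(res.cov_params, res.cov_params.T, atol=1e-14)
            assert np.linalg.eigvalsh(res.cov_params).min() > -1e-14

    def test_identity_link_reduces_to_least_squares(self):
        """With an identity mean model and IND basis the QIF minimizer is
        the OLS solution in closed form."""
        rng = np.random.default_rng(4)
        n, K, L = 60, 3, 4
        X = rng.normal(size=(n, K, L))
        X[:, :, 0] = 1.0
        truth = rng.normal(size=L)
        y = np.einsum("nkl,l->nk", X, truth) + rng.normal(scale=0.3, size=(n, K))
        design = pg.DesignSet(X=X, labels=[f"b{i}" for i in range(L)], P=L - K + 1)

        def mean_jac(beta):
            mu = np.einsum("nkl,l->nk", X, beta)
            return mu, np.broadcast_to(X, X.shape)

        beta, Q, converged, _ = _fit_qif(
            np.zeros(L), y, design, basis_set("ind", K), mean_jac
        )
        Xf = X.reshape(-1, L)
        ols = np.linalg.lstsq(Xf, y.ravel(), rcond=None)[0]
        assert converged
        np.testing.assert_allclose(beta, ols, atol=1e-8)

    def test_ind_equals_gee_across_datasets(self):
        rng = np.random.default_rng(12)
        sc = pg.Scenario(n=150, nsim=1)
        theta = pg.calibrate_censoring(0.2, -0.3, 0.6)
        for rep in range(20):
            s = pg.generate_trial(sc, seed=int(rng.integers(2**31)), theta=theta)
            grid = pg.select_time_grid(s, 5)
            po = pg.pseudo_obs_matrix(s, grid)
            d = pg.build_design(s, grid)
            gee = pg.PseudoGEE(po, d).fit()
            gmm = pg.PseudoGMM(po, d).fit()
            np.testing.assert_allclose(gmm.params, gee.params, atol=1e-6)
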