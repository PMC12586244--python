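"""Bayesian GMM tests: pseudo-likelihood, sampler, diagnostics, summaries."""

import numpy as np
import pytest

import pseudogmm as pg
from pseudogmm._mh import adaptive_rw_metropolis
from pseudogmm.bayes import PosteriorDraws, default_priors
from pseudogmm.gmm import basis_set, moment_state


@pytest.fixture(scope="module")
def mid_inputs():
    sc = pg.Scenario(n=150, nsim=1)
    s = pg.generate_trial(sc, seed=314, theta=pg.calibrate_censoring(0.2, -0.3, 0.6))
    grid = pg.select_time_grid(s, 5)
    po = pg.pseudo_obs_matrix(s, grid)
    return po, pg.build_design(s, grid)


class TestSigmaN:
    def test_rank_one_identity(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        beta = pg.starting_values(pseudo, design)
        for kind in ("ind", "exch"):
            basis = basis_set(kind, 5)
            S, _ = pg.sigma_n(beta, pseudo, design, basis)
            ms = moment_state(beta, pseudo, design, basis)
            np.testing.assert_allclose(
                S + np.outer(ms.U, ms.U) / design.n, ms.C, atol=1e-12
            )

    def test_equals_c_when_u_zero(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        gee = pg.PseudoGEE(pseudo, design).fit()
        basis = basis_set("ind", 5)
        S, ok = pg.sigma_n(gee.params, pseudo, design, basis)
        ms = moment_state(gee.params, pseudo, design, basis)
        np.testing.assert_allclose(S, ms.C, atol=1e-10)
        assert ok

    def test_flag_false_in_saturated_region(self, core_fit_inputs):
        pseudo, design = core_fit_inputs
        beta = np.zeros(design.L)
        beta[0] = 28.0
        _, ok = pg.sigma_n(beta, pseudo, design, basis_set("ind", 5))
        assert not ok


class TestLogPosterior:
    def test_local_max_near_frequentist_optimum(self, mid_inputs):
        pseudo, design = mid_inputs
        gmm = pg.PseudoGMM(pseudo, design).fit()
        priors = pg.PriorSpec("normal", 0.0, 10.0)
        basis = basis_set("ind", 5)

        def lp(b1):
            beta = gmm.params.copy()
            beta[1] = b1
            return pg.log_posterior(beta, pseudo, design, basis, priors)

        center = lp(gmm.params[1])
        assert center > lp(gmm.params[1] - 0.05)
        assert center > lp(gmm.params[1] + 0.05)

    def test_minus_infinity_outside_support(self, mid_inputs):
        pseudo, design = mid_inputs
        beta = np.zeros(design.L)
        beta[0] = 28.0
        lp = pg.log_posterior(beta, pseudo, design, "ind", pg.PriorSpec())
        assert lp == -np.inf

    def test_prior_term_closed_form(self, mid_inputs):
        pseudo, design = mid_inputs
        model = pg.BayesianPseudoGMM(
            pseudo, design, priors=pg.PriorSpec("normal", 0.0, 1.0)
        )
        lp_prior = model._log_prior_batch(np.zeros((1, design.L)))[0]
        assert lp_prior == pytest.approx(design.L * (-0.5 * np.log(2 * np.pi)))

    def test_default_prior_rule(self):
        assert default_priors(50).scale == 1.0
        assert default_priors(500).scale == 10.0


class TestStartingValuesSupport:
    def test_inside_support_across_datasets(self):
        theta = pg.calibrate_censoring(0.2, -0.3, 0.6)
        sc = pg.Scenario(n=100, nsim=1)
        priors = pg.PriorSpec("normal", 0.0, 1.0)
        for rep in range(25):
            s = pg.generate_trial(sc, seed=500 + rep, theta=theta)
            grid = pg.select_time_grid(s, 5)
            po = pg.pseudo_obs_matrix(s, grid)
            d = pg.build_design(s, grid)
            for eps in (0.01, 0.05, 0.1):
                beta = pg.starting_values(po, d, eps)
                lp = pg.log_posterior(beta, po, d, "ind", priors)
                assert np.isfinite(lp)


class TestSampler:
    def test_seeded_determinism(self, mid_inputs):
        pseudo, design = mid_inputs
        kw = dict(chains=3, iters=300, warmup=100, thin=5, seed=99)
        d1 = pg.sample_posterior(pseudo, design, "ind", None, **kw)
        d2 = pg.sample_posterior(pseudo, design, "ind", None, **kw)
        np.testing.assert_array_equal(d1.draws, d2.draws)
        assert d1.support_rejections == d2.support_rejections

    def test_recovers_known_gaussian_target(self):
        """Sampler validation against an analytic 6-dim normal target."""
        rng = np.random.default_rng(21)
        A = rng.normal(size=(6, 6))
        cov = A @ A.T / 6 + np.eye(6)
        mean = rng.normal(size=6)
        prec = np.linalg.inv(cov)

        def logpost(x):
            d = x - mean
            return -0.5 * np.einsum("ci,ij,cj->c", d, prec, d)

        x0 = np.tile(mean, (4, 1)) + rng.normal(scale=0.1, size=(4, 6))
        res = adaptive_rw_metropolis(
            logpost, x0, iters=20000, warmup=3000, thin=4,
            rng=np.random.default_rng(5),
        )
        draws = res.draws.reshape(-1, 6)
        se = np.sqrt(np.diag(cov)) / np.sqrt(pg.bulk_ess(res.draws))
        np.testing.assert_array_less(np.abs(draws.mean(axis=0) - mean), 5 * se)
        np.testing.assert_allclose(
            draws.std(axis=0), np.sqrt(np.diag(cov)), rtol=0.15
        )

    def test_posterior_agrees_with_frequentist_gmm(self, mid_inputs):
        pseudo, design = mid_inputs
        gmm = pg.PseudoGMM(pseudo, design).fit()
        res = pg.BayesianPseudoGMM(pseudo, design).fit(seed=6)
        assert abs(res.params[1] - gmm.params[1]) < 2 * res.bse[1]
        assert np.all(res.rhat < 1.1)

    def test_stalled_sampler_aborts(self):
        # warmup=0: no adaptation can rescue a proposal scale that is far
        # too wide for a tiny support
        def logpost(x):
            return np.where(np.abs(x).max(axis=1) < 1e-6, 0.0, -np.inf)

        with pytest.raises(RuntimeError, match="acceptance"):
            adaptive_rw_metropolis(
                logpost, np.zeros((2, 3)), iters=300, warmup=0,
                rng=np.random.default_rng(0), init_step=1.0,
            )


class TestDiagnostics:
    def test_identical_chains_give_exact_unit_rhat(self):
        rng = np.random.default_rng(2)
        chain = rng.normal(size=(1, 400, 3))
        draws = np.concatenate([chain, chain, chain], axis=0)
        np.testing.assert_allclose(pg.split_rhat(draws), 1.0, atol=1e-12)

    def test_shifted_chains_flagged(self):
        rng = np.random.default_rng(3)
        c1 = rng.normal(loc=-1.0, size=(1, 500, 2))
        c2 = rng.normal(loc=1.0, size=(1, 500, 2))
        assert np.all(pg.split_rhat(np.concatenate([c1, c2])) > 1.1)

    def test_iid_draws_have_near_total_ess(self):
        rng = np.random.default_rng(4)
        draws = rng.normal(size=(3, 800, 2))
        ess = pg.bulk_ess(draws)
        assert np.all(ess > 0.5 * 3 * 800)

    def test_matches_arviz_loosely(self):
        import arviz as az

        rng = np.random.default_rng(5)
        # AR(1) chains: autocorrelated, so ESS < total
        draws = np.empty((4, 1000, 1))
        for c in range(4):
            e = rng.normal(size=1000)
            x = np.empty(1000)
            x[0] = e[0]
            for t in range(1, 1000):
                x[t] = 0.7 * x[t - 1] + e[t]
            draws[c, :, 0] = x
        ours = pg.bulk_ess(draws)[0]
        theirs = float(az.ess(az.convert_to_dataset(draws[:, :, 0])).x)
        assert ours == pytest.approx(theirs, rel=0.25)
        assert pg.split_rhat(draws)[0] == pytest.approx(
            float(az.rhat(az.convert_to_dataset(draws[:, :, 0])).x), abs=0.02
        )


class TestPosteriorSummary:
    def _draws(self, arr):
        return PosteriorDraws(
            draws=arr, warmup=0, thin=1, seed=None,
            support_rejections=0, accept_rate=0.3,
        )

    def test_constant_draws(self):
        arr = np.full((2, 50, 2), 0.5)
        res = pg.posterior_summary(self._draws(arr), thresholds=(0.0,))
        assert res.params[1] == res.median[1] == 0.5
        np.testing.assert_array_equal(res.conf_int()[1], [0.5, 0.5])
        assert res.tail_probs[0.0][0] == 0.0

    def test_standard_normal_tail_probability(self):
        rng = np.random.default_rng(8)
        arr = rng.normal(size=(2, 4000, 2))
        res = pg.posterior_summary(self._draws(arr), thresholds=(0.0,))
        p, se = res.tail_probs[0.0]
        assert p == pytest.approx(0.5, abs=0.03)
        assert 0 < se < 0.05

    def test_interval_is_empirical_percentiles(self):
        rng = np.random.default_rng(9)
        arr = rng.normal(size=(3, 500, 2))
        res = pg.posterior_summary(self._draws(arr))
        stacked = arr.reshape(-1, 2)
        np.testing.assert_allclose(
            res.conf_int()[:, 0], np.percentile(stacked, 2.5, axis=0), atol=1e-12
        )
        np.testing.assert_allclose(
            res.conf_int()[:, 1], np.percentile(stacked, 97.5, axis=0), atol=1e-12
        )
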