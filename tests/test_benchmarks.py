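"""Cox and piecewise-exponential benchmark tests."""

import numpy as np
import pytest

import pseudogmm as pg
from pseudogmm.benchmarks import _breslow_loglik



class TestCox:
    def test_one_dim_grid_oracle(self):
        """n=4, no ties: the Newton solution maximizes the partial
        likelihood found by a fine 1-d grid search."""
        s = pg.SurvivalSample(
            ids=np.arange(4),
            time=[1.0, 2.0, 3.0, 4.0],
            status=[1, 1, 1, 1],
            covariates=np.array([1.0, 0.0, 1.0, 0.0])[:, None],
        )
        res = pg.fit_cox(s)
        grid = np.linspace(-3, 3, 20001)
        lls = [_breslow_loglik(np.array([b]), s.covariates, s.time, s.status)[0]
               for b in grid]
        assert res.params[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)
        # Newton refinement beats every grid point
        assert res.objective >= max(lls) - 1e-10

    def test_matches_reference_libraries_on_random_data(self):
        import pandas as pd
        from lifelines import CoxPHFitter
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(40, 120))
            # continuous times: no ties, Breslow == Efron
            time = rng.exponential(1.0, size=n)
            status = (rng.uniform(size=n) > 0.3).astype(int)
            status[0] = 1
            arm = rng.integers(0, 2, size=n).astype(float)
            s = pg.SurvivalSample(np.arange(n), time, status, arm[:, None])
            ours = pg.fit_cox(s)
            y = np.array(
                list(zip(status.astype(bool), time)),
                dtype=[("e", bool), ("t", float)],
            )
            ref = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200)
            ref.fit(arm[:, None], y)
            assert ours.params[0] == pytest.approx(ref.coef_[0], abs=1e-6)
            # lifelines converges to its looser default precision
            df = pd.DataFrame({"T": time, "E": status, "arm": arm})
            ll = CoxPHFitter().fit(df, "T", "E")
            assert ours.params[0] == pytest.approx(ll.params_.iloc[0], abs=1e-3)
            assert ours.bse[0] == pytest.approx(
                ll.standard_errors_.iloc[0], abs=1e-3
            )

    def test_large_sample_consistency(self):
        sc = pg.Scenario(n=4000, nsim=1, target_cr=0.0)
        s = pg.generate_trial(sc, seed=3)
        res = pg.fit_cox(s)
        assert abs(res.params[0] + 0.3) < 3 * res.bse[0]

    def test_monotone_likelihood_flagged(self):
        # all events in one arm, none in the other: likelihood is monotone
        time = np.r_[np.linspace(0.1, 1.0, 10), np.full(10, 2.0)]
        status = np.r_[np.ones(10, dtype=int), np.zeros(10, dtype=int)]
        arm = np.r_[np.ones(10), np.zeros(10)]
        s = pg.SurvivalSample(np.arange(20), time, status, arm[:, None])
        res = pg.fit_cox(s)
        assert not res.converged


class TestPEMSpec:
    def _sample_with_events(self, r, extra_censored=5):
        rng = np.random.default_rng(r)
        time = np.r_[rng.uniform(0.1, 5.0, size=r), np.full(extra_censored, 6.0)]
        status = np.r_[np.ones(r, dtype=int), np.zeros(extra_censored, dtype=int)]
        arm = (np.arange(r + extra_censored) % 2).astype(float)
        return pg.SurvivalSample(np.arange(time.size), time, status, arm[:, None])

    @pytest.mark.parametrize("r,expected_m", [(160, 20), (30, 5), (400, 20), (80, 10)])
    def test_interval_count_rule(self, r, expected_m):
        spec = pg.pem_spec(self._sample_with_events(r))
        assert spec.M == expected_m

    def test_cutpoints_balance_events(self):
        s = self._sample_with_events(200)
        spec = pg.pem_spec(s)
        events = np.sort(s.time[s.status == 1])
        counts = np.histogram(events, np.r_[0, spec.cutpoints, np.inf])[0]
        assert counts.max() - counts.min() <= 2  # type-1 quantiles: off-by-one per side

    def test_hhat_is_exponential_rate_mle(self):
        s = self._sample_with_events(50)
        spec = pg.pem_spec(s)
        assert spec.hhat == pytest.approx(50 / s.time.sum())


class TestPEMFit:
    def test_gibbs_matches_conjugate_closed_form(self, core_sample):
        """With beta fixed and a single interval, the hazard posterior is
        Gamma(1 + r, h_hat + total time) in closed form."""
        spec1 = pg.PEMSpec(
            M=1, cutpoints=np.empty(0), hhat=pg.pem_spec(core_sample).hhat
        )
        model = pg.PiecewiseExponentialModel(core_sample, spec1)
        res = model.fit(
            chains=2, iters=4000, warmup=100, seed=12,
            fix_beta=np.zeros(1), store_hazards=True,
        )
        h = np.asarray(res.extra["hazard_draws"]).ravel()
        shape = 1 + core_sample.n_events
        rate = spec1.hhat + core_sample.time.sum()
        mean_se = np.sqrt(shape) / rate / np.sqrt(h.size)
        assert abs(h.mean() - shape / rate) < 5 * mean_se
        assert h.var() == pytest.approx(shape / rate**2, rel=0.1)

    def test_exponential_data_single_interval_consistency(self):
        sc = pg.Scenario(n=3000, a=1.0, nsim=1, target_cr=0.0)
        s = pg.generate_trial(sc, seed=8)
        spec = pg.PEMSpec(M=1, cutpoints=np.empty(0), hhat=pg.pem_spec(s).hhat)
        res = pg.PiecewiseExponentialModel(s, spec).fit(
            chains=2, iters=1500, warmup=500, seed=4
        )
        assert abs(res.params[0] + 0.3) < 3 * res.bse[0]

    def test_core_scenario_fit_reasonable(self, core_sample):
        res = pg.PiecewiseExponentialModel(core_sample).fit(seed=2)
        cox = pg.fit_cox(core_sample)
        assert abs(res.params[0] - cox.params[0]) < 2 * res.bse[0]
        assert np.all(res.rhat < 1.1)

    def test_empty_interval_merged(self):
        # cutpoint beyond every observed time leaves an empty last interval
        time = np.linspace(0.1, 1.0, 30)
        s = pg.SurvivalSample(
            np.arange(30), time, np.ones(30, dtype=int),
            (np.arange(30) % 2).astype(float)[:, None],
        )
        spec = pg.PEMSpec(M=3, cutpoints=np.array([0.5, 5.0]), hhat=1.0)
        with pytest.warns(UserWarning, match="merging"):
            model = pg.PiecewiseExponentialModel(s, spec)
        assert model.spec.M == 2
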