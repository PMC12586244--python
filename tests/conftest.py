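import numpy as np
import pytest

import pseudogmm as pg


def random_censored_sample(rng, n, censor_frac=0.35):
    """Small mixed-censoring sample with ties possible."""
    time = np.round(rng.exponential(1.0, size=n), 2) + 0.01
    status = (rng.uniform(size=n) > censor_frac).astype(int)
    if status.sum() == 0:
        status[rng.integers(n)] = 1
    arm = rng.integers(0, 2, size=n).astype(float)
    return pg.SurvivalSample(
        ids=np.arange(n), time=time, status=status, covariates=arm[:, None]
    )


@pytest.fixture(scope="session")
def core_theta():
    """Censoring bound for the core scenario (20% censoring, log HR -0.3)."""
    return pg.calibrate_censoring(0.2, -0.3, 0.6)


@pytest.fixture(scope="session")
def core_sample(core_theta):
    """One simulated core-scenario trial: n=500, 20% censoring, log HR -0.3."""
    sc = pg.Scenario(n=500, nsim=1)
    return pg.generate_trial(sc, seed=20260928, theta=core_theta)


@pytest.fixture(scope="session")
def core_fit_inputs(core_sample):
    grid = pg.select_time_grid(core_sample, 5)
    pseudo = pg.pseudo_obs_matrix(core_sample, grid)
    design = pg.build_design(core_sample, grid)
    return pseudo, design
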