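# pseudogmm

Hazard-ratio inference from right-censored survival data via **jackknife
pseudo-observations** and the **generalized method of moments (GMM)** —
frequentist (quadratic inference functions) and Bayesian (moment
pseudo-likelihood MCMC) — with Cox, GEE and Bayesian piecewise-exponential
benchmarks and a clinical-trial simulation harness.

## The problem

Bayesian survival regression normally requires modelling the baseline
hazard (piecewise-exponential, splines, Gamma processes, ...), dragging in
nuisance parameters just to estimate a treatment hazard ratio.
Pseudo-observations sidestep the baseline hazard entirely: for subject *i*
and time *t_k*,

    y_ik = n * S(t_k) - (n-1) * S^{-i}(t_k),

where `S` is the Kaplan–Meier estimator and `S^{-i}` its leave-one-out
refit. The y_ik behave like complete-data versions of the survival
indicators `1{T_i > t_k}` (exactly equal to them when there is no
censoring), so censored data turn into an ordinary regression problem.
Under proportional hazards, the marginal model with the complementary
log-log link

    cloglog E(y_ik | X_i) = log H_0(t_k) + X_i' beta,
    cloglog(x) = log(-log x),

makes `beta_1` (the treatment coefficient) a Cox log hazard ratio. Time
enters as K−1 dummies over a K-point quantile grid of the event times
(K = 5 by default).

The classical fit is GEE, which has no likelihood and hence no Bayesian
analogue. This package instead stacks basis-matrix moment conditions
(independence / exchangeable / AR-1 expansions of the inverse working
correlation) into a per-subject score `u_i(beta)` and

- **frequentist GMM** minimizes the quadratic inference function
  `Q_n = U_n' C_n^{-1} U_n` with `U_n = mean(u_i)`,
  `C_n = n^{-2} Σ u_i u_i'`;
- **Bayesian GMM** samples the pseudo-posterior
  `exp(-½ U_n' Σ_n^{-1} U_n) × prior(beta)`,
  `Σ_n = C_n − n^{-1} U_n U_n'`, by adaptive random-walk Metropolis —
  proposals in the region where `Σ_n` degenerates (the restricted support
  of the pseudo-likelihood) are rejected in place.

Intended users: biostatisticians analysing two-arm (optionally
covariate-adjusted) time-to-event trials who want posterior tail
probabilities such as `P(log HR < log 1.43)` without committing to a
baseline-hazard model.

## Worked example

```python
import numpy as np
import pseudogmm as pg

# simulate a two-arm trial: n=500, 20% censoring, true log HR -0.3
sc = pg.Scenario(n=500, beta1=-0.3, target_cr=0.2, nsim=1)
sample = pg.generate_trial(sc, seed=11)

gmm = pg.PseudoGMM.from_sample(sample, K=5, basis="ind").fit()
print(gmm.summary())

bayes = pg.BayesianPseudoGMM.from_sample(sample, K=5).fit(
    seed=1, thresholds=(0.0,)
)
print(bayes.summary())
```

prints (abridged):

```
GMM (IND) fit (n=500)
converged: True  iterations: 6  objective: 3.69778e-17
             coef      se  ci_low  ci_high
intercept -1.8095  0.1295 -2.0633  -1.5557
treatment -0.3054  0.1147 -0.5302  -0.0806
time2      0.7893  0.0966  0.5999   0.9786
...
Bayesian GMM (IND) fit (n=500; 3 chains x 1000 kept draws, warmup 1000, thin 5)
acceptance rate: 0.203  support rejections: 0
             mean  median      sd  ci_low  ci_high    rhat       ess
...
treatment -0.3062 -0.3076  0.1103 -0.5156  -0.0753  1.0033  584.1380
...
P(beta_treatment < 0) = 0.997 (MC SE 0.002)
```

The `treatment` row is the log hazard ratio: the frequentist GMM estimate
−0.31 (SE 0.11, true value −0.30) and the posterior mean −0.31 with an
equal-tailed 95% credible interval excluding 0; the trailing line is the
posterior probability that the treatment reduces the hazard. Benchmarks:
`pg.fit_cox(sample)`, `pg.PseudoGEE.from_sample(sample).fit()` and
`pg.PiecewiseExponentialModel(sample).fit(seed=1)` expose the same
results API.

A command line mirrors the library:

```sh
pseudogmm simulate --n 500 --cr 0.2 --loghr -0.3 --seed 1 --out trial.csv
pseudogmm fit-gmm  --input trial.csv --K 5 --basis ind --out gmm.json
pseudogmm fit-bayes --input trial.csv --seed 1 --threshold 0 --out bayes.json
pseudogmm study --config study.yaml --out metrics.csv
```

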