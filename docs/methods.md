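# Methods

## Pseudo-observations

For right-censored i.i.d. survival times the jackknife pseudo-value of the
Kaplan–Meier survival probability at time t_k is
`y_ik = n Ŝ(t_k) − (n−1) Ŝ^{−i}(t_k)`. Ties between events and censorings
at the same time are resolved events-first (the standard product-limit
risk-set convention), and curves are evaluated right-continuously.
`pseudo_obs_matrix` avoids n leave-one-out refits by writing each
`Ŝ^{−i}` as a ratio of shared cumulative products over the distinct event
times: removing subject i shifts the at-risk count by one at every event
time where i was at risk, and the death count at i's own event time. Zero
factors (when a risk set is wiped out) are tracked separately from the log
accumulation so Kaplan–Meier curves that hit zero stay exact. The literal
n-refit `pseudo_obs_bruteforce` is kept as the reference oracle; the two
agree to 1e-10 on randomized inputs in the test suite.

The evaluation grid is the type-1 (inverse ECDF) empirical quantile of the
observed event times at probabilities k/(K+1), k = 1..K, so the K+1
induced intervals hold equal event counts as nearly as a deterministic rule
allows. Ties can collapse grid points; the grid then shrinks and flags
itself. Published sensitivity analyses (and ours) show results are
insensitive to K in the 5–10 range; K = 5 is the default. No grid point
ever exceeds the last observed event time, where pseudo-values are
undefined.

## Mean model

The marginal model applies the complementary log-log link to the survival
scale so that the treatment coefficient is a Cox log hazard ratio. The
design per subject and time point is: intercept; treatment indicator; K−1
time dummies with t_1 as the reference level (the intercept absorbs
log H_0(t_1)); and any extra baseline covariates repeated across time
points, giving L = P + K − 1 parameters. Linear predictors are clipped to
±30 before exponentiation — this keeps μ = exp(−exp(η)) strictly inside
(0,1) in double precision without affecting any realistic hazard-ratio
scale — and the Jacobian rows are the analytic −exp(η)·μ·X.

## GEE

Fisher scoring on `Σ D_i' R(α)^{-1} (y_i − μ_i) = 0` with an identity
variance function: pseudo-values fall outside [0,1], so no mean–variance
relation is imposed and residuals enter raw. α (exchangeable or AR-1) is
re-estimated between β steps by moment formulas standardized by the pooled
residual scale φ = mean(r²) — the literature does not fix this
standardization for pseudo-values; ours uses no degrees-of-freedom
corrections and clamps estimates to the valid range with a warning.
Uncertainty is the usual sandwich Γ0^{-1} Γ1 Γ0^{-1} with empirical
middles; Wald intervals use normal quantiles. The approximate-jackknife
variance popular for pseudo-value GEE is intentionally not implemented
(the estimators coincide for large samples, which is the regime the
package's asymptotics address). Step-halving (max 20) guards score-norm
increases; convergence is max|Δβ| < 1e-8 within 100 iterations.

## Frequentist GMM / QIF

The inverse working correlation is expanded over J basis matrices (IND:
{I}; EXCH: {I, ones−I}; AR-1: {I, first off-diagonals}); the stacked score
`u_i = [D_i'M_j(y_i−μ_i)]_j` has J·L components and the estimator
minimizes `Q_n = U_n' C_n^{-1} U_n`. The expansion coefficients a_j are
never estimated — the weighting absorbs them. Minimization is Gauss-Newton
(the second-derivative-of-U terms are dropped from the Hessian, the
standard QIF algorithm) with C_n refreshed each outer iteration, held
fixed within a step, and step-halving on the full objective, which makes
descent monotone. Starting values default to the truncated-cloglog OLS
procedure described under starting values below.

**Degenerate moment spectra.** When covariates are cluster-constant with
two levels — exactly the two-arm no-covariate trial — the EXCH and AR-1
stacked scores are linearly dependent: the second EXCH block equals
`S_i c_i − b_i` with `c_i` taking a single value per arm, so C_n has exact
rank 8 (EXCH) or 10 (AR-1) out of 12 at K=5. C_n^{-1} is therefore an
eigen-truncated pseudo-inverse (relative truncation 1e-12), and a moment
vector with a significant component outside the numerical range of C_n is
treated as out of support. Beyond the exact nulls, the kept spectrum still
spans several orders of magnitude, and inverting near-noise eigenvalues
makes the finite-sample QIF chase directions whose variance cannot be
estimated — the classic weak-moment overfitting of empirically weighted
GMM, which we observed as standard errors well below the replicate spread.
The weighting therefore adds a noise-floor ridge τ = λ_max·d/n (d = J·L)
to the kept eigenvalues: directions well above the sampling-error floor of
the second-moment matrix are essentially unaffected, directions below it
stop dominating. The reported covariance is the robust sandwich for the
weight actually used, `(G'WG)^{-1} G'W C_n W G (G'WG)^{-1}` with
`G = ∂U_n/∂β'` analytic (including the ∂D/∂β term). Under independence the
problem is exactly identified, the minimizer solves U_n = 0 regardless of
W, and the sandwich collapses to the GEE form — so the GEE ≡ GMM-IND
identity holds to solver tolerance by construction. A corollary of the
rank deficiency: the over-identification statistic Q(β̂) follows a
chi-squared law with rank−L (not (J−1)·L) degrees of freedom in this
design, and with the ridge the weak over-identifying directions contribute
almost nothing, so its replicate mean is far below (J−1)·L.

## Bayesian GMM

Since U_n(β) is asymptotically normal with variance consistently estimated
by `Σ_n = C_n − n^{-1} U_n U_n'` (the centered second moment), the moment
pseudo-likelihood `exp(−½ U_n' Σ_n^{-1} U_n)` combined with priors on β
yields a samplable pseudo-posterior. The quadratic form uses the strict
truncated pseudo-inverse — no ridge: softening the weak-direction penalty
flattens the support boundary and lets chains drift into saturated-mean
regions (we observed split-R̂ ≈ 1.15 when the ridge was applied here).
Proposals where Σ_n has no positive spectrum, or where U_n leaves its
numerical range, get log-density −∞ and are rejected in place; this is the
natural Metropolis treatment of the restricted support.

Priors are weakly informative on the cloglog scale: N(0,1) for n ≤ 100 and
N(0,10) otherwise (scale = standard deviation), overridable per
coefficient, with Cauchy(0, 2.5) available. Vague priors such as
N(0, 1000) are deliberately not defaults — they put mass on absurd
hazard-ratio scales and aggravate support excursions.

**Sampler.** Adaptive random-walk Metropolis rather than a gradient-based
sampler: the pseudo-likelihood has a hard non-invertibility boundary where
gradients are undefined, and boundary rejection is exactly MH behavior.
During warmup each chain adapts (i) a global scale toward the 0.234
optimal acceptance rate and (ii) a full proposal covariance from its
accumulated warmup draws (Cholesky factor, jittered); adaptation freezes
after warmup. The shaped proposal matters: the intercept and time-dummy
coordinates are strongly correlated, and a diagonal proposal yields
roughly a third of the bulk ESS at the same settings. Defaults follow the
reference settings: 3 chains × 5000 post-warmup iterations, warmup 1000,
thinning 5 (3000 kept draws). All chains advance in lock-step through one
batched density evaluation per iteration.

**Starting values.** Per chain: clamp pseudo-values to [ε, 1−ε]
(ε = 0.01 / 0.05 / 0.1 across the three chains), apply cloglog
elementwise, run OLS on the design. This is deliberately not a consistent
estimator (truncation bias; link applied to observations, not means;
correlation ignored) — it only needs to land inside the support, which it
does empirically on every simulated dataset we tested. Chains whose start
still falls outside retry with ε = 0.03.

Diagnostics are split-R̂ and Geyer-truncated bulk ESS; byte-identical
chains (no mixing signal) report R̂ = 1 by convention. Summaries are
posterior mean (the point estimate used in the simulation metrics;
median is also reported), equal-tailed 95% intervals from the stacked
thinned chains, and tail probabilities P(β_treatment < c) with Monte-Carlo
standard error sqrt(p(1−p)/ESS).

## Benchmarks

*Cox:* own Newton–Raphson on the Breslow partial likelihood with
step-halving and Wald SEs from the inverse observed information; monotone
likelihoods (e.g. no events in one arm) return a flagged, non-converged
fit. Against reference implementations on tie-free data the coefficients
agree to 1e-6 (our convergence is tighter than lifelines' default).

*Piecewise exponential (PEM):* interval count M = max{5, min(r/8, 20)}
from the event count r, cutpoints at event-time quantiles (equal events
per interval — the count rule fixes M but not placement; quantile
placement gives equal-information intervals), baseline priors
h_m ~ Gamma(1, ĥ) in shape–rate form with ĥ the exponential-model event
rate (a documented convention; the source parameterization is ambiguous),
and β ~ N(0, variance 1e5). Sampling interleaves exact Gamma-conjugate
Gibbs draws for the h_m with componentwise adaptive Metropolis for β
(0.44 target acceptance for the scalar updates). Intervals with zero
exposure are merged into their left neighbor with a warning. Defaults:
3 chains × 2000 kept iterations after 1000 warmup.

## Simulation engine

Event times are Weibull with shape a = 0.6 and scale exp(−β1·arm/a), so
the hazard ratio is exactly exp(β1) and the control median is
(ln 2)^{1/a} ≈ 0.543 time units (≈ 6.5 months on a yearly scale).
Allocation is balanced and fixed (⌊n/2⌋ treated) — minimal allocation
noise for a randomized two-arm trial. Censoring is uniform on (0, θ) with
θ solved by Brent root-finding on the analytically integrated (incomplete
gamma) censoring probability of the equal-weight arm mixture; a zero
target returns +∞ (no censoring). Accuracy is verified by direct
Monte-Carlo in the tests (10^6 draws, ±0.002).

The study runner replays a scenario nsim times (per-replicate seed =
base_seed + index, everything bit-reproducible), computes the pseudo-value
pipeline once per replicate, fits the requested methods, and aggregates
bias, average SE (ASE), replicate SD (ASD, n−1 denominator), RMSE and 95%
interval coverage, plus Monte-Carlo SEs for bias and coverage.
Non-convergent fits are dropped per cell with counts reported; cells
losing more than 5% are flagged. With the n−1 convention the identity
RMSE² = bias² + ((nsim−1)/nsim)·ASD² holds exactly and is property-tested.

What the generator does *not* emulate: covariate-dependent censoring
(which would violate the pseudo-value unbiasedness assumptions),
additional prognostic covariates (the fitters accept them; the generator
exercises the two-arm design), staggered accrual, and informative dropout.
Passing simulation tests therefore demonstrate internal validity of the
estimators under the stated sampling design, not robustness to those
real-data features.

## Problem sizes and reproducibility

The packaged test suite and `scripts/acceptance.py` run the study at desk
scale as the package's own verification budget: 500 replicates for
frequentist cells, 100–200 for MCMC cells, with the reference sampler
settings unchanged (chains are vectorized inside one fit, which is an
implementation detail, not an approximation). Monte-Carlo noise at those
counts is ~0.005 on bias and ~1–2 percentage points on coverage, and test
tolerances are set accordingly. All randomness flows from explicit seeds;
two runs with the same seeds are bit-identical.

## Known limitations

- EXCH/AR-1 weighting in the two-level cluster-constant design rests on
  the rank-truncated, ridged spectrum described above; with richer
  covariates C_n is full rank and the machinery reduces to textbook QIF.
- The Bayesian model is a pseudo-likelihood: it supports posterior
  inference on β but not prediction or model-based simulation.
- Working correlation choices are limited to IND/EXCH/AR-1; arbitrary
  user bases are out of scope.
- Pseudo-observations here target the survival probability only (hazard
  ratios); RMST, competing-risk and interval-censored variants are not
  implemented.
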