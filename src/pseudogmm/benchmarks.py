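"""Benchmark models: Cox proportional hazards and the Bayesian piecewise
exponential model (PEM).

The Cox fitter maximizes the Breslow partial likelihood by Newton-Raphson
with Wald standard errors from the inverse information.  The PEM assumes a
constant baseline hazard h_m on each of M intervals (M chosen from the
event count as max{5, min(r/8, 20)}, cutpoints at event-time quantiles),
with conjugate Gamma(1, h_hat) priors on the h_m — h_hat being the
exponential-model event rate — and a vague normal prior (variance 1e5) on
the log hazard ratio.  Sampling interleaves exact Gamma-conjugate Gibbs
updates for the hazards with adaptive Metropolis updates for beta.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .diagnostics import bulk_ess, split_rhat
from .pseudo import SurvivalSample
from .results import BayesianResults, FrequentistResults

__all__ = ["fit_cox", "PEMSpec", "pem_spec", "PiecewiseExponentialModel"]


def _breslow_loglik(beta, Z, time, status):
    """Breslow partial log-likelihood with gradient and Hessian."""
    n, p = Z.shape
    order = np.argsort(time, kind="stable")
    t, d, Zs = time[order], status[order], Z[order]
    eta = Zs @ beta
    w = np.exp(eta)
    zw = Zs * w[:, None]
    zzw = Zs[:, :, None] * Zs[:, None, :] * w[:, None, None]
    # risk-set sums: everyone with time >= t  (reverse cumulative sums)
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(zw[::-1], axis=0)[::-1]
    S2 = np.cumsum(zzw[::-1], axis=0)[::-1]
    ev_times = np.unique(t[d == 1])
    first = np.searchsorted(t, ev_times, side="left")
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    for j, tj in zip(first, ev_times):
        at = (t == tj) & (d == 1)
        dj = at.sum()
        s0, s1, s2 = S0[j], S1[j], S2[j]
        ll += eta[at].sum() - dj * np.log(s0)
        m1 = s1 / s0
        grad += Zs[at].sum(axis=0) - dj * m1
        hess -= dj * (s2 / s0 - np.outer(m1, m1))
    return ll, grad, hess


def fit_cox(sample: SurvivalSample, maxiter: int = 50, tol: float = 1e-10) -> FrequentistResults:
    """Cox model on all covariates; Breslow ties, Newton-Raphson.

    A monotone partial likelihood (e.g. no events in one arm) is returned
    as a flagged (non-converged) fit rather than an exception.
    """
    Z = sample.covariates
    beta = np.zeros(Z.shape[1])
    converged = False
    it = 0
    ll, grad, hess = _breslow_loglik(beta, Z, sample.time, sample.status)
    for it in range(1, maxiter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            ll2, g2, h2 = _breslow_loglik(cand, Z, sample.time, sample.status)
            if ll2 >= ll - 1e-12:
                beta, ll, grad, hess = cand, ll2, g2, h2
                break
            lam *= 0.5
        if np.max(np.abs(lam * step)) < tol:
            converged = True
            break
        if np.max(np.abs(beta)) > 15:  # monotone likelihood divergence
            break
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.full((Z.shape[1],) * 2, np.nan)
        converged = False
    return FrequentistResults(
        params=beta,
        cov_params=cov,
        labels=list(sample.covariate_names),
        method="Cox (Breslow)",
        nobs=sample.n,
        converged=converged,
        n_iter=it,
        objective=float(ll),
    )


@dataclass
class PEMSpec:
    """Interval partition and priors for the piecewise exponential model."""

    M: int
    cutpoints: np.ndarray  # M-1 interior boundaries
    hhat: float  # exponential-model MLE of the event rate
    gamma_shape: float = 1.0
    beta_prior_var: float = 1e5

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.M < 1 or self.cutpoints.size != self.M - 1:
            raise ValueError("need M-1 ascending interior cutpoints")
        if self.cutpoints.size and np.any(np.diff(self.cutpoints) <= 0):
            raise ValueError("cutpoints must be strictly ascending")


def pem_spec(sample: SurvivalSample) -> PEMSpec:
    """Murray-style interval count M = max{5, min(r/8, 20)} with cutpoints
    at event-time quantiles (equal event counts per interval)."""
    r = sample.n_events
    if r < 1:
        raise ValueError("need at least one event")
    M = int(max(5, min(r / 8.0, 20)))
    events = np.sort(sample.time[sample.status == 1])
    if M > 1:
        probs = np.arange(1, M) / M
        cuts = np.unique(np.quantile(events, probs, method="inverted_cdf"))
        M = cuts.size + 1
    else:
        cuts = np.empty(0)
    hhat = r / float(sample.time.sum())
    return PEMSpec(M=M, cutpoints=cuts, hhat=hhat)


class PiecewiseExponentialModel:
    """Bayesian PEM with proportional covariate effects exp(Z beta)."""

    def __init__(self, sample: SurvivalSample, spec: PEMSpec | None = None) -> None:
        self.sample = sample
        self.spec = spec if spec is not None else pem_spec(sample)
        edges = np.concatenate([[0.0], self.spec.cutpoints, [np.inf]])
        t = sample.time
        # exposure of subject i in interval m and the event interval index
        lo = edges[:-1][None, :]
        hi = edges[1:][None, :]
        self.exposure = np.clip(np.minimum(t[:, None], hi) - lo, 0.0, None)
        ev_idx = np.searchsorted(self.spec.cutpoints, t[sample.status == 1], side="left")
        self.d_m = np.bincount(ev_idx, minlength=self.spec.M).astype(float)
        # merge intervals with no exposure into their left neighbor
        empty = self.exposure.sum(axis=0) <= 0
        if empty.any():
            warnings.warn("merging PEM interval(s) with zero exposure", stacklevel=2)
            keep = ~empty
            self.exposure = self.exposure[:, keep]
            self.d_m = self.d_m[keep]
            self.spec = PEMSpec(
                M=int(keep.sum()),
                cutpoints=self.spec.cutpoints[keep[1:]] if keep.size > 1 else np.empty(0),
                hhat=self.spec.hhat,
                beta_prior_var=self.spec.beta_prior_var,
            )

    def _hazard_posterior(self, beta: np.ndarray):
        """Conjugate Gamma parameters for h_m given beta: shape, rate."""
        lam = np.exp(self.sample.covariates @ beta)
        rate = self.spec.hhat + self.exposure.T @ lam
        return self.spec.gamma_shape + self.d_m, rate

    def fit(
        self,
        chains: int = 3,
        iters: int = 2000,
        warmup: int = 1000,
        thin: int = 1,
        seed: int | None = None,
        thresholds: tuple = (),
        fix_beta: np.ndarray | None = None,
        store_hazards: bool = False,
    ) -> BayesianResults:
        Z = self.sample.covariates
        n, p = Z.shape
        M = self.spec.M
        delta = self.sample.status == 1
        dZ = Z[delta].sum(axis=0)
        kept = iters // thin
        beta_draws = np.empty((chains, kept, p))
        h_draws = np.empty((chains, kept, M)) if store_hazards else None
        accepts = 0
        ss = np.random.SeedSequence(seed)
        for c, child in enumerate(ss.spawn(chains)):
            rng = np.random.default_rng(child)
            beta = np.zeros(p) if fix_beta is None else np.asarray(fix_beta, float).copy()
            scale = np.full(p, 0.1)
            win_acc = np.zeros(p)
            kidx = 0
            for t in range(warmup + iters):
                shape, rate = self._hazard_posterior(beta)
                h = rng.gamma(shape) / rate
                if fix_beta is None:
                    eh = self.exposure @ h  # (n,)
                    lam = np.exp(Z @ beta)
                    ll = dZ @ beta - lam @ eh - 0.5 * beta @ beta / self.spec.beta_prior_var
                    for j in range(p):  # componentwise MH
                        cand = beta.copy()
                        cand[j] += rng.normal(0.0, scale[j])
                        lam_c = np.exp(Z @ cand)
                        ll_c = (
                            dZ @ cand
                            - lam_c @ eh
                            - 0.5 * cand @ cand / self.spec.beta_prior_var
                        )
                        if np.log(rng.uniform()) < ll_c - ll:
                            beta, ll = cand, ll_c
                            win_acc[j] += 1
                            if t >= warmup:
                                accepts += 1
                    if t < warmup and (t + 1) % 50 == 0:
                        scale *= np.exp(1.2 * (win_acc / 50.0 - 0.44))
                        win_acc[:] = 0.0
                if t >= warmup and (t - warmup + 1) % thin == 0:
                    beta_draws[c, kidx] = beta
                    if store_hazards:
                        h_draws[c, kidx] = h
                    kidx += 1
        if chains >= 2:
            rhat, ess = split_rhat(beta_draws), bulk_ess(beta_draws)
        else:
            rhat = np.full(p, np.nan)
            ess = np.full(p, float(chains * kept))
        res = BayesianResults(
            draws=beta_draws,
            labels=list(self.sample.covariate_names),
            method="Bayesian PEM",
            nobs=n,
            rhat=rhat,
            ess=ess,
            warmup=warmup,
            thin=thin,
            seed=seed,
            accept_rate=accepts / max(chains * iters * p, 1) if fix_beta is None else np.nan,
            treatment_index=0,
            extra={"M": M, "hhat": self.spec.hhat},
        )
        if store_hazards:
            res.extra["hazard_draws"] = h_draws
        res.tail_probs = {float(cst): res.tail_probability(float(cst)) for cst in thresholds}
        return res
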