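"""Adaptive random-walk Metropolis sampler.

Gaussian random-walk proposals whose shape is adapted during warmup: a
per-chain proposal covariance is estimated from the accumulated warmup
draws (so correlated posteriors mix at the same rate as spherical ones)
and a per-chain global scale is tuned toward the 0.234 optimal acceptance
rate.  All adaptation freezes at the end of warmup.  Proposals whose
log-target is -inf (outside the support of a restricted pseudo-likelihood)
are rejected in place and counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MHResult", "adaptive_rw_metropolis"]

TARGET_ACCEPT = 0.234
ADAPT_WINDOW = 50


@dataclass
class MHResult:
    draws: np.ndarray  # (chains, kept, L)
    accept_rate: float  # post-warmup, all chains pooled
    support_rejections: int
    scales: np.ndarray  # frozen per-chain global scales


def adaptive_rw_metropolis(
    logpost,
    x0: np.ndarray,
    iters: int,
    warmup: int,
    thin: int = 1,
    rng: np.random.Generator | None = None,
    init_step: float | np.ndarray = 0.05,
    min_accept: float = 0.01,
) -> MHResult:
    """Run ``iters`` post-warmup iterations of adaptive RW Metropolis.

    ``logpost`` maps a (chains, L) batch of states to (chains,) log densities
    (-inf outside the support).  All chains advance in lock-step so the
    per-iteration cost is one batched density evaluation.
    """
    rng = np.random.default_rng(rng)
    x = np.array(x0, dtype=float, copy=True)
    if x.ndim != 2:
        raise ValueError("x0 must be (chains, L)")
    C, L = x.shape
    lp = np.asarray(logpost(x), dtype=float)
    if np.any(~np.isfinite(lp)):
        raise ValueError("initial states must have finite log posterior")

    # proposal: x + scale_c * (F_c z), F_c a Cholesky factor of the adapted
    # per-chain covariance (initially diagonal from init_step)
    scale = np.full(C, 2.38 / np.sqrt(L))
    step0 = np.broadcast_to(np.asarray(init_step, dtype=float), (C, L))
    F = np.zeros((C, L, L))
    for c in range(C):
        F[c] = np.diag(step0[c])

    kept = iters // thin
    draws = np.empty((C, kept, L))
    warm_buf = np.empty((warmup, C, L)) if warmup else None
    support_rej = 0
    acc_post = 0
    window_acc = np.zeros(C)
    kidx = 0

    total = warmup + iters
    for t in range(total):
        z = rng.standard_normal((C, L))
        prop = x + scale[:, None] * np.einsum("cij,cj->ci", F, z)
        lp_prop = np.asarray(logpost(prop), dtype=float)
        support_rej += int(np.sum(np.isneginf(lp_prop)))
        logu = np.log(rng.uniform(size=C))
        accept = logu < (lp_prop - lp)
        x[accept] = prop[accept]
        lp[accept] = lp_prop[accept]

        if t < warmup:
            window_acc += accept
            warm_buf[t] = x
            if (t + 1) % ADAPT_WINDOW == 0:
                rate = window_acc / ADAPT_WINDOW
                scale *= np.exp(1.2 * (rate - TARGET_ACCEPT))
                if t + 1 >= 4 * L:  # enough draws to shape the proposal
                    hist = warm_buf[max(0, t + 1 - 500) : t + 1]
                    for c in range(C):
                        cov = np.cov(hist[:, c, :], rowvar=False)
                        jitter = 1e-6 * max(np.trace(cov) / L, 1e-12)
                        try:
                            F[c] = np.linalg.cholesky(cov + jitter * np.eye(L))
                        except np.linalg.LinAlgError:
                            pass  # keep previous factor
                window_acc[:] = 0.0
        else:
            acc_post += int(accept.sum())
            s = t - warmup
            if (s + 1) % thin == 0:
                draws[:, kidx] = x
                kidx += 1

    accept_rate = acc_post / (C * iters) if iters else np.nan
    if iters and accept_rate < min_accept:
        raise RuntimeError(
            f"sampler stalled: post-warmup acceptance {accept_rate:.4f} < {min_accept}; "
            "check starting values / priors against the pseudo-likelihood support"
        )
    return MHResult(
        draws=draws[:, :kidx],
        accept_rate=accept_rate,
        support_rejections=support_rej,
        scales=scale,
    )
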