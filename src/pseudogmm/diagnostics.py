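"""MCMC convergence diagnostics: split R-hat and bulk effective sample size."""

from __future__ import annotations

import numpy as np

__all__ = ["split_rhat", "bulk_ess", "diagnostics"]


def _split_chains(draws: np.ndarray) -> np.ndarray:
    """(C, N, ...) -> (2C, N//2, ...), dropping a trailing odd draw."""
    C, N = draws.shape[:2]
    half = N // 2
    return np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)


def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Split-R̂ per parameter for draws of shape (chains, N, L).

    Chains are split in half; R̂ = sqrt(((N-1)/N · W + B/N) / W) with W the
    mean within-chain variance and B/N the variance of the chain means.
    Degenerate cases — all chains identical, or zero between- or
    within-chain variance — are reported as exactly 1.0.
    """
    draws = np.asarray(draws, dtype=float)
    if np.all(draws == draws[:1]):  # identical chains carry no mixing signal
        return np.ones(draws.shape[-1])
    x = _split_chains(draws)
    C, N, L = x.shape
    means = x.mean(axis=1)  # (C, L)
    W = x.var(axis=1, ddof=1).mean(axis=0)  # (L,)
    B_over_N = means.var(axis=0, ddof=1)  # (L,)
    out = np.ones(L)
    ok = (W > 0) & (B_over_N > 0)
    vhat = (N - 1) / N * W[ok] + B_over_N[ok]
    out[ok] = np.sqrt(vhat / W[ok])
    return out


def _autocov(x: np.ndarray) -> np.ndarray:
    """Biased autocovariance of a 1-d series via FFT."""
    n = x.shape[0]
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    return acov / n


def bulk_ess(draws: np.ndarray) -> np.ndarray:
    """Effective sample size with Geyer's initial monotone sequence.

    Uses split chains; rho_t = 1 - (W - mean_c acov_{c,t}) / vhat, summed over
    pairs until the first negative pair sum, with the pair sums forced
    non-increasing.
    """
    x = _split_chains(np.asarray(draws, dtype=float))
    C, N, L = x.shape
    total = C * N
    out = np.empty(L)
    for l in range(L):
        W = x[:, :, l].var(axis=1, ddof=1).mean()
        if W == 0:
            out[l] = total
            continue
        means = x[:, :, l].mean(axis=1)
        B_over_N = means.var(ddof=1) if C > 1 else 0.0
        vhat = (N - 1) / N * W + B_over_N
        acov = np.mean([_autocov(x[c, :, l]) for c in range(C)], axis=0)
        rho = 1.0 - (W - acov) / vhat
        rho[0] = 1.0
        # Geyer pairs
        tau = -1.0
        prev = np.inf
        m = 0
        while 2 * m + 1 < N:
            pair = rho[2 * m] + rho[2 * m + 1]
            if pair < 0:
                break
            pair = min(pair, prev)
            tau += 2.0 * pair
            prev = pair
            m += 1
        out[l] = min(total, total / max(tau, 1.0 / total))
    return out


def diagnostics(draws: np.ndarray) -> dict:
    """Per-coefficient split-R̂ and bulk ESS for (chains, N, L) draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 3 or draws.shape[0] < 2:
        raise ValueError("diagnostics need draws of shape (chains >= 2, N, L)")
    return {"rhat": split_rhat(draws), "ess": bulk_ess(draws)}
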