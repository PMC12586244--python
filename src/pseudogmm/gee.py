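"""Generalized estimating equations for pseudo-observations.

Marginal cloglog model fitted by Fisher scoring on the score equations

    U_n(beta) = (1/n) sum_i D_i' R^{-1}(alpha) (y_i - mu_i) = 0,

with an identity variance function (raw residuals: pseudo-values fall
outside [0, 1], so no mean-variance relation is imposed).  The working
correlation R(alpha) is independence, exchangeable, or AR-1; alpha is
re-estimated from standardized residual cross-products between beta steps.
Uncertainty comes from the usual sandwich Gamma0^{-1} Gamma1 Gamma0^{-1}.
"""

from __future__ import annotations

import warnings

import numpy as np

from .design import DesignSet, build_design, mean_and_jacobian, starting_values
from .pseudo import PseudoObservationMatrix, SurvivalSample, pseudo_obs_matrix, select_time_grid
from .results import FrequentistResults

__all__ = ["PseudoGEE", "estimate_alpha", "working_correlation"]

STRUCTURES = ("ind", "exch", "ar1")


def estimate_alpha(residuals: np.ndarray, kind: str) -> float:
    """Moment estimator of the working-correlation parameter.

    Standardizes by the common residual scale phi = mean(r^2) over all
    cells; EXCH averages all within-subject pairs k < l, AR-1 the lag-1
    pairs.  Estimates outside the valid range are clamped with a warning.
    """
    r = np.asarray(residuals, dtype=float)
    n, K = r.shape
    if K < 2:
        return 0.0
    phi = np.mean(r**2)
    if phi <= 0:
        return 0.0
    if kind == "exch":
        total = 0.5 * ((r.sum(axis=1) ** 2 - (r**2).sum(axis=1)).sum())
        alpha = total / (n * K * (K - 1) / 2.0) / phi
        lo, hi = -1.0 / (K - 1), 1.0
    elif kind == "ar1":
        alpha = np.mean(r[:, :-1] * r[:, 1:]) / phi
        lo, hi = -1.0, 1.0
    else:
        raise ValueError(f"unknown working structure {kind!r}")
    eps = 1e-6
    if not (lo + eps <= alpha <= hi - eps):
        warnings.warn(
            f"alpha estimate {alpha:.4f} outside ({lo}, {hi}); clamped",
            stacklevel=2,
        )
        alpha = float(np.clip(alpha, lo + eps, hi - eps))
    return float(alpha)


def working_correlation(kind: str, alpha: float, K: int) -> np.ndarray:
    if kind == "ind":
        return np.eye(K)
    if kind == "exch":
        return (1.0 - alpha) * np.eye(K) + alpha * np.ones((K, K))
    if kind == "ar1":
        idx = np.arange(K)
        return alpha ** np.abs(idx[:, None] - idx[None, :])
    raise ValueError(f"unknown working structure {kind!r}")


class PseudoGEE:
    """GEE model for an n x K pseudo-observation matrix.

    Parameters
    ----------
    pseudo : PseudoObservationMatrix
    design : DesignSet
    structure : 'ind' | 'exch' | 'ar1' working correlation.
    """

    def __init__(
        self,
        pseudo: PseudoObservationMatrix,
        design: DesignSet,
        structure: str = "ind",
    ) -> None:
        if structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if pseudo.values.shape[:1] + (pseudo.grid.K,) != (design.n, design.K):
            raise ValueError("pseudo-observations and design are not conformable")
        self.pseudo = pseudo
        self.design = design
        self.structure = structure

    @classmethod
    def from_sample(
        cls, sample: SurvivalSample, K: int = 5, structure: str = "ind"
    ) -> "PseudoGEE":
        grid = select_time_grid(sample, K)
        pseudo = pseudo_obs_matrix(sample, grid)
        return cls(pseudo, build_design(sample, grid), structure)

    def _score_and_info(self, beta, Rinv):
        y = self.pseudo.values
        mu, D = mean_and_jacobian(beta, self.design)
        r = y - mu
        DR = np.einsum("nkl,km->nml", D, Rinv)  # (n, K, L): R^{-1} D_i
        score = np.einsum("nkl,nk->l", DR, r) / self.design.n
        info = np.einsum("nkl,nkm->lm", DR, D) / self.design.n
        return score, info, r

    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 100,
        tol: float = 1e-8,
    ) -> FrequentistResults:
        """Fisher scoring with step-halving, alternating alpha updates."""
        n, K, L = self.design.n, self.design.K, self.design.L
        beta = (
            np.asarray(start, dtype=float)
            if start is not None
            else starting_values(self.pseudo, self.design)
        )
        alpha = 0.0
        Rinv = np.eye(K)
        converged = False
        it = 0
        score, info, resid = self._score_and_info(beta, Rinv)
        for it in range(1, maxiter + 1):
            if self.structure != "ind":
                alpha = estimate_alpha(resid, self.structure)
                Rinv = np.linalg.inv(working_correlation(self.structure, alpha, K))
                score, info, resid = self._score_and_info(beta, Rinv)
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise ValueError("design rank deficient") from exc
            snorm = np.linalg.norm(score)
            # step-halving on score-norm increase
            lam, accepted = 1.0, False
            for _ in range(20):
                cand = beta + lam * step
                s2, i2, r2 = self._score_and_info(cand, Rinv)
                if np.linalg.norm(s2) <= snorm or lam == 1.0 and snorm < tol:
                    beta, score, info, resid = cand, s2, i2, r2
                    accepted = True
                    break
                lam *= 0.5
            if not accepted:
                break
            if np.max(np.abs(lam * step)) < tol:
                converged = True
                break

        # sandwich covariance at the solution
        mu, D = mean_and_jacobian(beta, self.design)
        r = self.pseudo.values - mu
        DR = np.einsum("nkl,km->nml", D, Rinv)
        G0 = np.einsum("nkl,nkm->lm", DR, D) / n
        Sr = np.einsum("nkl,nk->nl", DR, r)  # D_i' R^{-1} r_i per subject
        G1 = Sr.T @ Sr / n
        try:
            G0inv = np.linalg.inv(G0)
        except np.linalg.LinAlgError as exc:
            raise ValueError("design rank deficient") from exc
        cov = G0inv @ G1 @ G0inv / n
        cov = 0.5 * (cov + cov.T)
        return FrequentistResults(
            params=beta,
            cov_params=cov,
            labels=self.design.labels,
            method=f"GEE ({self.structure.upper()})",
            nobs=n,
            converged=converged,
            n_iter=it,
            objective=float(np.linalg.norm(score)),
            extra={"alpha": float(alpha), "structure": self.structure},
        )
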