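"""Frequentist GMM via the quadratic inference function (QIF).

The inverse working correlation is expanded over J basis matrices,
R^{-1} ~ sum_j a_j M_j, and the per-subject extended score stacks

    u_i(beta) = [ D_i' M_1 (y_i - mu_i); ...; D_i' M_J (y_i - mu_i) ],

a J*L vector.  The combination coefficients a_j are never estimated — the
QIF weighting absorbs them.  With U_n = mean(u_i) and
C_n = (1/n^2) sum_i u_i u_i', the estimator minimizes

    Q_n(beta) = U_n' C_n^{-1} U_n,

by a Gauss-Newton iteration (C_n refreshed each outer step, held fixed
within a step), and its covariance is the Hansen sandwich
[ (dU/dbeta)' C_n^{-1} (dU/dbeta) ]^{-1} (already O(1/n) under the moment
normalisation used here).  Under independence (J=1) the minimizer solves
U_n = 0 and coincides with GEE.  C_n^{-1} is an eigen-truncated
pseudo-inverse: for cluster-constant covariates the EXCH/AR-1 stacked
scores are exactly linearly dependent, so C_n is structurally singular.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import DesignSet, build_design, mean_and_jacobian, starting_values
from .pseudo import PseudoObservationMatrix, SurvivalSample, pseudo_obs_matrix, select_time_grid
from .results import FrequentistResults

__all__ = ["BasisSet", "basis_set", "MomentState", "moment_state", "qif", "PseudoGMM"]

#: reciprocal-condition guard below which C_n / Sigma_n count as singular
RCOND_GUARD = 1e-12


@dataclass
class BasisSet:
    """Symmetric 0/1 basis matrices expanding an inverse working correlation."""

    kind: str
    matrices: list[np.ndarray]

    @property
    def J(self) -> int:
        return len(self.matrices)


def basis_set(kind: str, K: int) -> BasisSet:
    """IND -> {I}; EXCH -> {I, ones - I}; AR1 -> {I, first off-diagonals}."""
    if kind == "ind":
        return BasisSet(kind, [np.eye(K)])
    if K < 2:
        raise ValueError(f"basis {kind!r} requires K >= 2")
    if kind == "exch":
        return BasisSet(kind, [np.eye(K), np.ones((K, K)) - np.eye(K)])
    if kind == "ar1":
        m2 = np.zeros((K, K))
        idx = np.arange(K - 1)
        m2[idx, idx + 1] = 1.0
        m2[idx + 1, idx] = 1.0
        return BasisSet(kind, [np.eye(K), m2])
    raise ValueError(f"unknown basis kind {kind!r}")


@dataclass
class MomentState:
    """Extended score U_n, its empirical second moment C_n, per-subject scores."""

    U: np.ndarray
    C: np.ndarray
    u: np.ndarray  # (n, J*L)


def _scores(resid: np.ndarray, D: np.ndarray, basis: BasisSet) -> np.ndarray:
    """Per-subject stacked scores u_i, shape (n, J*L)."""
    parts = [np.einsum("nkl,nk->nl", D, resid @ M.T) for M in basis.matrices]
    return np.concatenate(parts, axis=1)


def moment_state(
    beta: np.ndarray,
    pseudo: PseudoObservationMatrix,
    design: DesignSet,
    basis: BasisSet,
) -> MomentState:
    mu, D = mean_and_jacobian(beta, design)
    u = _scores(pseudo.values - mu, D, basis)
    n = design.n
    U = u.mean(axis=0)
    C = u.T @ u / n**2
    return MomentState(U=U, C=C, u=u)


#: tolerated squared fraction of U outside the numerical range of C_n
RANGE_TOL = 1e-8


def _ridge(w_max: float, d: int, n: int) -> float:
    """Weighting ridge at the sampling-noise floor of the empirical
    second-moment matrix.

    The eigenvalues of C_n carry an estimation error of relative order d/n,
    so moment directions whose variance sits below lambda_max * d / n cannot
    be weighted reliably; the ridge caps their weight instead of letting
    1/lambda explode (the classic weak-moment overfitting of empirically
    weighted GMM).  Directions with eigenvalues well above the floor are
    essentially unaffected.
    """
    return w_max * d / n


def _eig_psd(C: np.ndarray, n: int, rcond: float = RCOND_GUARD):
    """Eigendecomposition of C_n with truncation mask and weighting ridge.

    Returns (w, V, keep, tau) or None when the matrix has no positive
    spectrum.  Eigenvalues below ``rcond`` times the largest are truncated:
    with cluster-constant covariates (e.g. a two-arm trial with no extra
    covariates) the stacked EXCH/AR-1 scores are exactly linearly dependent,
    so C_n is structurally rank-deficient and its inverse must be understood
    as a Moore-Penrose pseudo-inverse on the score range.  On the kept
    directions, weighting uses 1/(lambda + tau) with the noise-floor ridge
    tau (see :func:`_ridge`).
    """
    w, V = np.linalg.eigh(C)
    if w[-1] <= 0:
        return None
    keep = w > rcond * w[-1]
    return w, V, keep, _ridge(w[-1], C.shape[0], n)


def _wsolve(eig, B: np.ndarray) -> np.ndarray:
    """Apply the ridged pseudo-inverse weight W = V (lambda+tau)^-1 V' to B."""
    w, V, keep, tau = eig
    Z = V.T @ B
    if B.ndim == 1:
        return V[:, keep] @ (Z[keep] / (w[keep] + tau))
    return V[:, keep] @ (Z[keep] / (w[keep] + tau)[:, None])


def _quadform(eig, U: np.ndarray) -> float:
    """U' W U, or +inf when U leaves the numerical range of C.

    A significant component of U in the null space of C means the moment
    vector cannot be weighted consistently (the out-of-support region);
    the objective is reported as +inf there.
    """
    w, V, keep, tau = eig
    z = V.T @ U
    tot = float(z @ z)
    if tot > 0:
        null = float(z[~keep] @ z[~keep])
        if null > RANGE_TOL * tot:
            return np.inf
    return float(np.sum(z[keep] ** 2 / (w[keep] + tau)))


def qif(
    beta: np.ndarray,
    pseudo: PseudoObservationMatrix,
    design: DesignSet,
    basis: BasisSet,
) -> float:
    """Quadratic inference function Q_n(beta); +inf outside the support."""
    ms = moment_state(beta, pseudo, design, basis)
    eig = _eig_psd(ms.C, design.n)
    if eig is None:
        return np.inf
    return _quadform(eig, ms.U)


def _dU_dbeta(beta, y, design, basis):
    """Analytic (J*L, L) derivative of U_n, including the dD/dbeta term."""
    mu, D, d2 = mean_and_jacobian(beta, design, second=True)
    resid = y - mu
    n = design.n
    blocks = []
    for M in basis.matrices:
        Mr = resid @ M.T  # (n, K)
        # -(1/n) sum D_i' M D_i  +  (1/n) sum_k (M r_i)_k mu''_ik x x'
        t1 = -np.einsum("nkl,km,nmj->lj", D, M, D) / n
        w = Mr * d2  # (n, K)
        t2 = np.einsum("nk,nkl,nkj->lj", w, design.X, design.X) / n
        blocks.append(t1 + t2)
    return np.vstack(blocks)


class PseudoGMM:
    """Quadratic-inference-function model for pseudo-observations."""

    def __init__(
        self,
        pseudo: PseudoObservationMatrix,
        design: DesignSet,
        basis: str | BasisSet = "ind",
    ) -> None:
        if pseudo.values.shape != (design.n, design.K):
            raise ValueError("pseudo-observations and design are not conformable")
        self.pseudo = pseudo
        self.design = design
        self.basis = basis if isinstance(basis, BasisSet) else basis_set(basis, design.K)

    @classmethod
    def from_sample(
        cls, sample: SurvivalSample, K: int = 5, basis: str = "ind"
    ) -> "PseudoGMM":
        grid = select_time_grid(sample, K)
        pseudo = pseudo_obs_matrix(sample, grid)
        return cls(pseudo, build_design(sample, grid), basis)

    def qif(self, beta: np.ndarray) -> float:
        return qif(beta, self.pseudo, self.design, self.basis)

    def fit(
        self,
        start: np.ndarray | None = None,
        maxiter: int = 100,
        qtol: float = 1e-10,
        btol: float = 1e-8,
    ) -> FrequentistResults:
        if start is None:
            start = starting_values(self.pseudo, self.design, epsilon=0.05)
        beta, Q, converged, it = _fit_qif(
            np.asarray(start, dtype=float),
            self.pseudo.values,
            self.design,
            self.basis,
            lambda b: mean_and_jacobian(b, self.design),
            maxiter=maxiter,
            qtol=qtol,
            btol=btol,
        )
        # Robust sandwich covariance at the optimum: the estimator solves
        # G' W U = 0 with the ridged weight W, so
        # cov = (G'WG)^{-1} G'W C_n W G (G'WG)^{-1}.  With U_n = mean(u_i)
        # and C_n = (1/n^2) sum u_i u_i' this is already O(1/n), and under
        # independence (square G, any W) it collapses to the GEE sandwich.
        ms = moment_state(beta, self.pseudo, self.design, self.basis)
        G = _dU_dbeta(beta, self.pseudo.values, self.design, self.basis)
        eig = _eig_psd(ms.C, self.design.n)
        if eig is None:
            raise ValueError("C_n degenerate at the optimum; covariance undefined")
        WG = _wsolve(eig, G)
        A = np.linalg.inv(G.T @ WG)
        cov = A @ (WG.T @ ms.C @ WG) @ A
        cov = 0.5 * (cov + cov.T)
        return FrequentistResults(
            params=beta,
            cov_params=cov,
            labels=self.design.labels,
            method=f"GMM ({self.basis.kind.upper()})",
            nobs=self.design.n,
            converged=converged,
            n_iter=it,
            objective=Q,
            extra={"basis": self.basis.kind, "J": self.basis.J},
        )


def _fit_qif(start, y, design, basis, mean_jac, maxiter=100, qtol=1e-10, btol=1e-8):
    """Gauss-Newton minimization of the QIF over a pluggable mean model.

    ``mean_jac(beta) -> (mu, D)`` defines the first moment; C_n is refreshed
    at each outer iteration and held fixed within the line search.  Descent
    is guaranteed by step-halving on the full (refreshed-C) objective.
    """
    n = design.n

    def state(beta):
        mu, D = mean_jac(beta)
        u = _scores(y - mu, D, basis)
        U = u.mean(axis=0)
        C = u.T @ u / n**2
        eig = _eig_psd(C, n)
        Q = np.inf if eig is None else _quadform(eig, U)
        return mu, D, U, eig, Q

    beta = np.asarray(start, dtype=float).copy()
    mu, D, U, eig, Q = state(beta)
    if not np.isfinite(Q):
        raise ValueError(
            "starting values lie outside the QIF support; "
            "use the truncated-cloglog starting_values procedure"
        )
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        G = _gn_dU(beta, y, design, basis, mu, D)
        grad = G.T @ _wsolve(eig, U)
        H = G.T @ _wsolve(eig, G)
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        lam, accepted = 1.0, False
        for _ in range(20):
            cand = beta + lam * step
            st = state(cand)
            if st[4] <= Q:
                beta, (mu, D, U, eig, Qnew) = cand, st
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            converged = Q < np.inf
            break
        if abs(Q - Qnew) < qtol or np.max(np.abs(lam * step)) < btol:
            Q = Qnew
            converged = True
            break
        Q = Qnew
    return beta, Q, converged, it


def _gn_dU(beta, y, design, basis, mu, D):
    """Gauss-Newton dU/dbeta' (drops the dD/dbeta term), (J*L, L)."""
    n = design.n
    return np.vstack(
        [-np.einsum("nkl,km,nmj->lj", D, M, D) / n for M in basis.matrices]
    )
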