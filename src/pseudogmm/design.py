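"""Marginal cloglog mean model for pseudo-observations.

Under proportional hazards, S(t_k | X_i) = S_0(t_k)^{exp(X_i' beta)}, so the
complementary log-log link g(x) = log(-log x) makes the model linear,

    g(mu_ik) = beta_0 + beta_1 * arm_i + beta_{k} * I{time = t_k, k >= 2} + ...

and the treatment coefficient beta_1 is a Cox log hazard ratio.  Time enters
as K-1 dummies (t_1 is the reference level absorbed in the intercept), extra
baseline covariates are repeated across time points, giving L = P + K - 1
parameters for P covariates (including the intercept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pseudo import PseudoObservationMatrix, SurvivalSample, TimeGrid

__all__ = [
    "DesignSet",
    "build_design",
    "cloglog",
    "inv_cloglog",
    "mean_and_jacobian",
    "starting_values",
]

#: linear predictors are clipped to +-ETA_CLIP before exponentiation so that
#: mu stays strictly inside (0, 1) in double precision
ETA_CLIP = 30.0


@dataclass
class DesignSet:
    """Per-subject, per-time covariate rows X_{ik}.

    ``X`` has shape (n, K, L), rows ordered intercept, treatment,
    time dummies I_2..I_K, then extra covariates.
    """

    X: np.ndarray
    labels: list[str]
    P: int  # covariate count including intercept

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ValueError("X must be (n, K, L)")
        if self.X.shape[2] != len(self.labels):
            raise ValueError("labels must match the number of columns")
        if self.L != self.P + self.K - 1:
            raise ValueError("L must equal P + K - 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]

    @property
    def L(self) -> int:
        return self.X.shape[2]

    @property
    def flat(self) -> np.ndarray:
        """(n*K, L) view, subject-major."""
        return self.X.reshape(-1, self.L)


def build_design(sample: SurvivalSample, grid: TimeGrid) -> DesignSet:
    """Intercept + treatment + K-1 time dummies + extra covariates."""
    arm = sample.covariates[:, 0]
    if not np.isin(arm, (0.0, 1.0)).all():
        raise ValueError("treatment column (first covariate) must be binary 0/1")
    n, K = sample.n, grid.K
    extras = sample.covariates[:, 1:]
    L = 2 + (K - 1) + extras.shape[1]
    X = np.zeros((n, K, L))
    X[:, :, 0] = 1.0
    X[:, :, 1] = arm[:, None]
    for k in range(1, K):
        X[:, k, 1 + k] = 1.0
    for j in range(extras.shape[1]):
        X[:, :, 1 + K + j] = extras[:, j][:, None]
    labels = (
        ["intercept", "treatment"]
        + [f"time{k + 1}" for k in range(1, K)]
        + list(sample.covariate_names[1:])
    )
    return DesignSet(X=X, labels=labels, P=2 + extras.shape[1])


def cloglog(x):
    """Complementary log-log link g(x) = log(-log(x)), x in (0, 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("cloglog is defined on (0, 1)")
    return np.log(-np.log(x))


def inv_cloglog(x):
    """Inverse link: exp(-exp(x)), mapping the reals into (0, 1)."""
    return np.exp(-np.exp(np.asarray(x, dtype=float)))


def mean_and_jacobian(beta: np.ndarray, design: DesignSet, second: bool = False):
    """Model means mu (n, K) and per-subject Jacobians D (n, K, L).

    D_i = d mu_i / d beta' has rows -exp(eta_ik) * mu_ik * X_ik.  With
    ``second=True`` also returns d^2 mu / d eta^2 = exp(eta)(exp(eta)-1)mu,
    needed for the analytic derivative of the GMM moment vector.
    """
    beta = np.asarray(beta, dtype=float)
    eta = np.clip(design.X @ beta, -ETA_CLIP, ETA_CLIP)
    s = np.exp(eta)
    mu = np.exp(-s)
    dmu = -s * mu
    D = dmu[:, :, None] * design.X
    if second:
        return mu, D, s * (s - 1.0) * mu
    return mu, D


def starting_values(
    pseudo: PseudoObservationMatrix, design: DesignSet, epsilon: float = 0.05
) -> np.ndarray:
    """Truncated-cloglog OLS starting values.

    Clamps the pseudo-values to [epsilon, 1-epsilon], applies the cloglog
    link elementwise, and regresses by ordinary least squares on the design.
    This is a rough initialiser only — it ignores the within-subject
    correlation and the truncation bias — but lands inside the support of
    the GMM pseudo-likelihood in practice.
    """
    if not (0.0 < epsilon < 0.5):
        raise ValueError("epsilon must lie in (0, 0.5)")
    y = np.clip(pseudo.values, epsilon, 1.0 - epsilon)
    z = cloglog(y).ravel()
    Xf = design.flat
    beta, _, rank, _ = np.linalg.lstsq(Xf, z, rcond=None)
    if rank < design.L:
        raise ValueError("design matrix is rank deficient")
    return beta
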