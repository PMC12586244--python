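"""Results containers shared by all fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FrequentistResults", "BayesianResults"]


@dataclass
class FrequentistResults:
    """Point estimates with a sandwich covariance and Wald intervals."""

    params: np.ndarray
    cov_params: np.ndarray
    labels: list[str]
    method: str
    nobs: int
    converged: bool = True
    n_iter: int = 0
    objective: float = np.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        self.cov_params = np.asarray(self.cov_params, dtype=float)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params), 0.0, None))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        return np.column_stack(
            [self.params - z * self.bse, self.params + z * self.bse]
        )

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=self.labels,
        )

    def summary(self) -> str:
        lines = [
            f"{self.method} fit (n={self.nobs})",
            f"converged: {self.converged}  iterations: {self.n_iter}"
            + (f"  objective: {self.objective:.6g}" if np.isfinite(self.objective) else ""),
            self.summary_frame().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "method": self.method,
            "nobs": int(self.nobs),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "objective": float(self.objective) if np.isfinite(self.objective) else None,
            "coefficients": [
                {
                    "label": lab,
                    "estimate": float(b),
                    "se": float(s),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                }
                for lab, b, s, lo, hi in zip(
                    self.labels, self.params, self.bse, ci[:, 0], ci[:, 1]
                )
            ],
            "extra": _jsonify(self.extra),
        }


@dataclass
class BayesianResults:
    """Posterior summaries from MCMC draws.

    ``draws`` has shape (chains, kept iterations, L); summaries are over the
    stacked, thinned chains.  ``tail_probs`` maps a threshold c to the
    posterior probability P(beta_treatment < c) with its Monte-Carlo SE.
    """

    draws: np.ndarray
    labels: list[str]
    method: str
    nobs: int
    rhat: np.ndarray
    ess: np.ndarray
    warmup: int
    thin: int
    seed: int | None = None
    support_rejections: int = 0
    accept_rate: float = np.nan
    tail_probs: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    treatment_index: int = 1

    @property
    def stacked(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def params(self) -> np.ndarray:
        """Posterior means (the default point estimate)."""
        return self.stacked.mean(axis=0)

    @property
    def median(self) -> np.ndarray:
        return np.median(self.stacked, axis=0)

    @property
    def bse(self) -> np.ndarray:
        """Posterior standard deviations."""
        return self.stacked.std(axis=0, ddof=1)

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Equal-tailed credible interval."""
        lo = np.percentile(self.stacked, 100 * alpha / 2.0, axis=0)
        hi = np.percentile(self.stacked, 100 * (1.0 - alpha / 2.0), axis=0)
        return np.column_stack([lo, hi])

    def tail_probability(self, threshold: float) -> tuple[float, float]:
        """P(beta_treatment < threshold) and its Monte-Carlo SE."""
        x = self.stacked[:, self.treatment_index]
        p = float(np.mean(x < threshold))
        neff = max(float(self.ess[self.treatment_index]), 1.0)
        return p, float(np.sqrt(p * (1.0 - p) / neff))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame(
            {
                "mean": self.params,
                "median": self.median,
                "sd": self.bse,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
                "rhat": self.rhat,
                "ess": self.ess,
            },
            index=self.labels,
        )

    def summary(self) -> str:
        lines = [
            f"{self.method} fit (n={self.nobs}; {self.draws.shape[0]} chains x "
            f"{self.draws.shape[1]} kept draws, warmup {self.warmup}, thin {self.thin})",
            f"acceptance rate: {self.accept_rate:.3f}  "
            f"support rejections: {self.support_rejections}",
            self.summary_frame().to_string(float_format=lambda v: f"{v: .4f}"),
        ]
        for c, (p, se) in self.tail_probs.items():
            lines.append(f"P(beta_treatment < {c:.4g}) = {p:.3f} (MC SE {se:.3f})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "method": self.method,
            "nobs": int(self.nobs),
            "chains": int(self.draws.shape[0]),
            "kept_iterations": int(self.draws.shape[1]),
            "warmup": int(self.warmup),
            "thin": int(self.thin),
            "seed": self.seed,
            "accept_rate": float(self.accept_rate),
            "support_rejections": int(self.support_rejections),
            "coefficients": [
                {
                    "label": lab,
                    "mean": float(m),
                    "median": float(md),
                    "sd": float(s),
                    "ci_low": float(lo),
                    "ci_high": float(hi),
                    "rhat": float(r),
                    "ess": float(e),
                }
                for lab, m, md, s, lo, hi, r, e in zip(
                    self.labels,
                    self.params,
                    self.median,
                    self.bse,
                    ci[:, 0],
                    ci[:, 1],
                    self.rhat,
                    self.ess,
                )
            ],
            "tail_probabilities": {
                str(c): {"prob": float(p), "mc_se": float(se)}
                for c, (p, se) in self.tail_probs.items()
            },
            "extra": _jsonify(self.extra),
        }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
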