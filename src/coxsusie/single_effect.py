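"""Single-effect regression (SER) for the Bayesian Cox model.

The SER assumes exactly one of p covariates has a non-zero log hazard
ratio, with a N(0, sigma0^2) prior on its size and a multinomial prior
pi over which covariate it is.  The posterior factorizes into three
p-vectors: alpha (which covariate), mu1 and sigma1sq (the effect's
Gaussian posterior given that covariate is the one).  Exact per-variable
Bayes factors are replaced by their Laplace approximations.

The prior variance sigma0^2 can be estimated by EM: the E-step is the
SER posterior itself, the M-step is

    sigma0^2  <-  sum_j alpha_j (mu1_j^2 + sigma1_j^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .bayes_factors import (NormalPrior, _log_laplace_bf_arrays,
                            _moments_arrays)
from .survival_core import SurvivalOutcome, batch_univariate_coxph

__all__ = [
    "SERPosterior",
    "alpha_from_log_bf",
    "coxph_ser",
    "em_update_sigma0sq",
    "ser_logml",
    "SIGMA0SQ_FLOOR",
]

#: Floor for the EM estimate of sigma0^2.  The M-step can collapse to 0
#: on null data; a floored value plus a null flag lets downstream purity
#: filtering discard the resulting uninformative credible set.
SIGMA0SQ_FLOOR = 1e-8


@dataclass(frozen=True)
class SERPosterior:
    """Posterior of the Cox single-effect regression on p covariates."""

    alpha: np.ndarray       # (p,) posterior inclusion within this effect
    mu1: np.ndarray         # (p,) posterior mean of b given variable j active
    sigma1sq: np.ndarray    # (p,) posterior variance of b given j active
    log_bf: np.ndarray      # (p,) per-variable log Laplace Bayes factor
    sigma0sq: float         # prior variance used for this fit
    prior_pi: np.ndarray    # (p,) prior inclusion probabilities
    loglik_null: float      # log l(0; ., c), shared across variables
    degenerate: np.ndarray = field(default=None)  # (p,) no-information mask

    @property
    def p(self) -> int:
        return len(self.alpha)

    @property
    def posterior_mean_effects(self) -> np.ndarray:
        """b-bar = alpha * mu1, the posterior-mean single effect vector."""
        return self.alpha * self.mu1

    @property
    def log_bf_ser(self) -> float:
        """Log Bayes factor of the whole SER against the null model."""
        with np.errstate(divide="ignore"):
            log_w = np.where(self.prior_pi > 0, np.log(self.prior_pi),
                             -np.inf) + self.log_bf
        return float(logsumexp(log_w))


def _normalize_pi(prior_pi, p: int) -> np.ndarray:
    if prior_pi is None:
        return np.full(p, 1.0 / p)
    pi = np.asarray(prior_pi, dtype=np.float64)
    if pi.shape != (p,):
        raise ValueError("prior_pi length must equal the number of columns")
    if np.any(pi < 0) or not np.isclose(pi.sum(), 1.0, atol=1e-8):
        raise ValueError("prior_pi must be non-negative and sum to 1")
    return pi / pi.sum()


def alpha_from_log_bf(log_bf: np.ndarray, prior_pi: np.ndarray) -> np.ndarray:
    """Posterior inclusion weights alpha_j proportional to pi_j * BF_j.

    Max-subtracted softmax in log space, so arbitrarily large Bayes
    factors (|z| in the hundreds) cannot overflow.
    """
    with np.errstate(divide="ignore"):
        log_w = np.where(prior_pi > 0, np.log(prior_pi), -np.inf) + log_bf
    w = np.exp(log_w - log_w.max())
    return w / w.sum()


def coxph_ser(X: np.ndarray, outcome: SurvivalOutcome,
              offset: np.ndarray | None = None,
              prior: NormalPrior = NormalPrior(1.0),
              prior_pi: np.ndarray | None = None,
              ties: str = "efron") -> SERPosterior:
    """Fit the Cox SER: univariate scan, Laplace BFs, softmax posterior.

    Each column gets an independent univariate Cox fit (vectorized across
    columns, so the scan is deterministic regardless of execution order),
    then alpha_j is proportional to pi_j * BF_j, computed by a
    max-subtracted softmax in log space.  If every column is degenerate
    the posterior falls back to the prior (alpha = pi, mu1 = 0).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be an n x p matrix")
    p = X.shape[1]
    pi = _normalize_pi(prior_pi, p)

    fits = batch_univariate_coxph(X, outcome, offset=offset, ties=ties)
    s2 = fits.se ** 2
    log_bf = _log_laplace_bf_arrays(fits.z, s2,
                                    fits.loglik_mle - fits.loglik_null,
                                    fits.degenerate, prior.variance)
    mu1, sigma1sq = _moments_arrays(fits.bhat, s2, prior.variance)
    mu1 = np.where(fits.degenerate, 0.0, mu1)
    sigma1sq = np.where(fits.degenerate, 0.0, sigma1sq)

    alpha = alpha_from_log_bf(log_bf, pi)

    return SERPosterior(alpha=alpha, mu1=mu1, sigma1sq=sigma1sq,
                        log_bf=log_bf, sigma0sq=prior.variance,
                        prior_pi=pi,
                        loglik_null=float(fits.loglik_null[0]),
                        degenerate=fits.degenerate)


def em_update_sigma0sq(ser: SERPosterior,
                       floor: float = SIGMA0SQ_FLOOR) -> tuple[float, bool]:
    """One EM M-step for the prior variance.

    Returns ``(sigma0sq_new, is_null)`` where ``is_null`` marks updates
    that collapsed to the floor — the signature of an effect with no
    support in the data.
    """
    value = float(np.sum(ser.alpha * (ser.mu1 ** 2 + ser.sigma1sq)))
    if value < floor:
        return floor, True
    return value, False


def ser_logml(ser: SERPosterior) -> float:
    """Approximate log marginal likelihood of the SER.

    log l_SER(sigma0^2) = logsumexp_j {log pi_j + log BF_j} + log l(0),
    the quantity the EM on sigma0^2 ascends.
    """
    with np.errstate(divide="ignore"):
        log_w = np.where(ser.prior_pi > 0, np.log(ser.prior_pi),
                         -np.inf) + ser.log_bf
    return float(logsumexp(log_w)) + ser.loglik_null
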