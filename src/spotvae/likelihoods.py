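"""Count likelihoods shared by signature estimation and the decoder model.

The negative binomial is parameterized by its mean ``mu`` and the
gene-specific inverse-dispersion ``beta``:

    pmf(x; mu, beta) = Gamma(x+beta) / (Gamma(beta) x!)
                       * (beta/(beta+mu))^beta * (mu/(beta+mu))^x

so Var[X] = mu + mu^2 / beta, and beta -> infinity recovers Poisson(mu).
This is the standard mean/inverse-dispersion convention of the single-cell
literature.
"""

from __future__ import annotations

import numpy as np
from scipy.special import digamma, gammaln

MU_FLOOR = 1e-8


def nb_logpmf(x: np.ndarray, mu: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Elementwise NB log-pmf; broadcasts; ``mu`` floored for finiteness."""
    x = np.asarray(x, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    beta = np.asarray(beta, dtype=float)
    return (
        gammaln(x + beta)
        - gammaln(beta)
        - gammaln(x + 1.0)
        + beta * (np.log(beta) - np.log(beta + mu))
        + x * (np.log(mu) - np.log(beta + mu))
    )


def nb_logpmf_grad_mu(x: np.ndarray, mu: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """d log NB / d mu, evaluated at the floored mu."""
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    return x / mu - (x + beta) / (beta + mu)


def nb_logpmf_grad_beta(x: np.ndarray, mu: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """d log NB / d beta."""
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    return (
        digamma(x + beta)
        - digamma(beta)
        + np.log(beta)
        - np.log(beta + mu)
        + 1.0
        - (x + beta) / (beta + mu)
    )


def poisson_logpmf(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    return x * np.log(mu) - mu - gammaln(x + 1.0)


def poisson_logpmf_grad_mu(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    return x / mu - 1.0


def zinb_logpmf(
    x: np.ndarray, mu: np.ndarray, beta: np.ndarray, tau: np.ndarray
) -> np.ndarray:
    """Zero-inflated NB log-pmf with per-gene dropout probability ``tau``.

    P(0) = tau + (1-tau) NB(0); P(x>0) = (1-tau) NB(x).
    """
    x = np.asarray(x, dtype=float)
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0 - 1e-12)
    nb = nb_logpmf(x, mu, beta)
    # log(tau + (1-tau) e^{nb0}) computed stably via logaddexp
    with np.errstate(divide="ignore"):
        log_tau = np.log(np.broadcast_to(tau, nb.shape))
    zero_case = np.logaddexp(log_tau, np.log1p(-tau) + nb)
    return np.where(x == 0, zero_case, np.log1p(-tau) + nb)


def zinb_logpmf_grad_mu(
    x: np.ndarray, mu: np.ndarray, beta: np.ndarray, tau: np.ndarray
) -> np.ndarray:
    """d log ZINB / d mu."""
    x = np.asarray(x, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), MU_FLOOR)
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0 - 1e-12)
    grad_nb = nb_logpmf_grad_mu(x, mu, beta)
    # zero case: d/dmu log(tau + (1-tau) p0), p0 = (beta/(beta+mu))^beta
    log_p0 = beta * (np.log(beta) - np.log(beta + mu))
    p0 = np.exp(log_p0)
    denom = tau + (1.0 - tau) * p0
    dzero = (1.0 - tau) * p0 * (-beta / (beta + mu)) / denom
    return np.where(x == 0, dzero, grad_nb)
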