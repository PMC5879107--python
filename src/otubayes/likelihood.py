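"""Negative-binomial likelihood in the (mean, overdispersion) parameterization.

Counts follow NB(mu, s) with E[y] = mu and Var[y] = mu + mu^2 s; the
OTU-specific overdispersion s_j > 0 lets variance exceed the mean, and the
model collapses to Poisson(mu) as s -> 0.  Equivalently y ~ NB(size = 1/s,
prob = 1/(1 + s mu)) in the classical (size, prob) form.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = ["nb_logpmf", "nb_loglik_mu_terms", "sample_nb"]


def nb_logpmf(y, mu, s):
    """Log pmf of NB(mean=mu, overdispersion=s); broadcasts over arrays.

    log P(y) = log Gamma(y + 1/s) - log Gamma(1/s) - log Gamma(y + 1)
               - (1/s) log(1 + s mu) + y [log(s mu) - log(1 + s mu)]
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(mu <= 0) or np.any(s <= 0):
        raise ValueError("mu and s must be strictly positive")
    inv_s = 1.0 / s
    log1sm = np.log1p(s * mu)
    out = (
        gammaln(y + inv_s)
        - gammaln(inv_s)
        - gammaln(y + 1.0)
        - inv_s * log1sm
        + y * (np.log(s) + np.log(mu) - log1sm)
    )
    return float(out) if out.ndim == 0 else out


def nb_loglik_mu_terms(y, log_mu, s):
    """The mu-dependent part of the NB log likelihood, elementwise.

    y log(mu) - (y + 1/s) log(1 + s mu), taking mu on the log scale.  The
    gamma-function terms depend only on (y, s) and cancel in any
    Metropolis ratio that changes mu alone, so every baseline/regression
    update uses this cheap form.
    """
    mu = np.exp(log_mu)
    return y * log_mu - (y + 1.0 / s) * np.log1p(s * mu)


def sample_nb(mu, s, rng: np.random.Generator, poisson_if_zero: bool = True):
    """Draw NB(mean=mu, overdispersion=s) deviates; s == 0 means Poisson."""
    mu = np.asarray(mu, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    zero = s == 0
    if np.any(zero):
        if not poisson_if_zero:
            raise ValueError("s must be > 0")
        out[zero] = rng.poisson(mu[zero])
    nz = ~zero
    if np.any(nz):
        size = 1.0 / s[nz]
        p = 1.0 / (1.0 + s[nz] * mu[nz])
        out[nz] = rng.negative_binomial(size, p)
    return out
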