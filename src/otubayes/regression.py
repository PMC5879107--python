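"""Covariate effects with Laplace (Bayesian-lasso) shrinkage.

Covariates act multiplicatively on the mean count through a log link,
``eta_j(X_t) = exp(X_t' beta_j)``, so a coefficient beta_{j,p} is read as
the log fold-change in the expected abundance of OTU j per unit (or per
level, for indicator columns) of covariate p.  The coefficients carry a
Laplace prior written as a scale mixture of normals,

    beta_{j,p} | sigma_j^2, phi_{j,p} ~ N(0, sigma_j^2 phi_{j,p})
    phi_{j,p} ~ Exp(lambda_j^2 / 2)
    lambda_j^2 ~ Ga(a_lam, b_lam),   sigma_j^2 ~ IG(a_sig, b_sig)

which marginalizes to Laplace(0, scale = sigma_j^2 / lambda_j).  The
mixture representation gives conjugate Gibbs updates for everything but
beta itself, which is non-conjugate under the negative-binomial
likelihood and is updated by adaptive random-walk Metropolis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import nb_loglik_mu_terms

__all__ = [
    "RegressionState",
    "eta",
    "laplace_marginal_logpdf",
    "update_phi",
    "update_lambda2",
    "update_sigma2",
    "update_beta",
    "update_beta_block",
]

_BETA_FLOOR = 1e-10  # |beta| clamp in the inverse-Gaussian mean


@dataclass
class RegressionState:
    """Coefficients and shrinkage scales for all J OTUs.

    beta and phi are (J, P); sigma2 (global scale) and lambda2 (squared
    Laplace rate) are per-OTU vectors of length J.
    """

    beta: np.ndarray
    sigma2: np.ndarray
    lambda2: np.ndarray
    phi: np.ndarray
    a_lam: float = 0.5
    b_lam: float = 0.5
    a_sig: float = 0.3
    b_sig: float = 0.3

    def __post_init__(self) -> None:
        self.beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        self.phi = np.atleast_2d(np.asarray(self.phi, dtype=float))
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        self.lambda2 = np.asarray(self.lambda2, dtype=float)
        if np.any(self.sigma2 <= 0) or np.any(self.lambda2 <= 0) or np.any(self.phi <= 0):
            raise ValueError("sigma2, lambda2 and phi must be strictly positive")

    @property
    def J(self) -> int:
        return self.beta.shape[0]

    @property
    def P(self) -> int:
        return self.beta.shape[1]

    @classmethod
    def from_prior(
        cls,
        J: int,
        P: int,
        rng: np.random.Generator,
        a_lam: float = 0.5,
        b_lam: float = 0.5,
        a_sig: float = 0.3,
        b_sig: float = 0.3,
    ) -> "RegressionState":
        lambda2 = rng.gamma(a_lam, 1.0 / b_lam, size=J)
        sigma2 = 1.0 / rng.gamma(a_sig, 1.0 / b_sig, size=J)
        phi = rng.exponential(2.0 / lambda2[:, None], size=(J, P))
        beta = rng.normal(0.0, np.sqrt(sigma2[:, None] * phi))
        return cls(beta, sigma2, lambda2, phi, a_lam, b_lam, a_sig, b_sig)


def eta(x: np.ndarray, beta_j: np.ndarray) -> float:
    """Multiplicative covariate effect ``exp(x' beta_j)`` on the mean count."""
    return float(np.exp(np.dot(np.asarray(x, float), np.asarray(beta_j, float))))


def laplace_marginal_logpdf(beta, lambda2: float, sigma2: float):
    """Log density of the phi-marginalized prior: Laplace(0, sigma/lambda).

    Integrating the scale mixture N(beta; 0, sigma2 phi) Exp(phi; lambda2/2)
    over phi gives f(beta) = lambda/(2 sigma) exp(-lambda |beta| / sigma)
    with lambda = sqrt(lambda2), sigma = sqrt(sigma2): the classical
    Bayesian-lasso marginal, whose scale sigma/lambda shrinks as the rate
    lambda grows.
    """
    if lambda2 <= 0 or sigma2 <= 0:
        raise ValueError("lambda2 and sigma2 must be positive")
    lam = np.sqrt(lambda2)
    sig = np.sqrt(sigma2)
    return np.log(lam / (2.0 * sig)) - lam * np.abs(beta) / sig


def update_phi(state: RegressionState, j: int, rng: np.random.Generator) -> RegressionState:
    """Gibbs draw of the local scales phi_{j,.} from their full conditional.

    Standard Bayesian-lasso algebra: 1/phi_{j,p} | beta, lambda2, sigma2 ~
    InvGaussian(mean = sqrt(lambda2 sigma2 / beta^2), shape = lambda2).
    beta exactly zero is guarded by clamping |beta| away from zero.
    """
    b = np.maximum(np.abs(state.beta[j]), _BETA_FLOOR)
    mu_ig = np.sqrt(state.lambda2[j] * state.sigma2[j]) / b
    inv_phi = rng.wald(mu_ig, state.lambda2[j])
    state.phi[j] = 1.0 / inv_phi
    return state


def update_lambda2(state: RegressionState, j: int, rng: np.random.Generator) -> RegressionState:
    """Conjugate Gibbs draw: lambda2_j | phi ~ Ga(a+P, b + sum(phi)/2)."""
    shape = state.a_lam + state.P
    rate = state.b_lam + 0.5 * state.phi[j].sum()
    state.lambda2[j] = rng.gamma(shape, 1.0 / rate)
    return state

def update_sigma2(state: RegressionState, j: int, rng: np.random.Generator) -> RegressionState:
    """Conjugate Gibbs draw: sigma2_j | beta, phi ~ IG(a+P/2, b + sum(beta^2/phi)/2)."""
    shape = state.a_sig + 0.5 * state.P
    scale = state.b_sig + 0.5 * np.sum(state.beta[j] ** 2 / state.phi[j])
    state.sigma2[j] = scale / rng.gamma(shape)
    return state


def update_beta_block(
    beta: np.ndarray,
    X_samples: np.ndarray,
    counts: np.ndarray,
    log_offset: np.ndarray,
    s: np.ndarray,
    sigma2: np.ndarray,
    phi: np.ndarray,
    steps: np.ndarray,
    rng: np.random.Generator,
    adapt: float | None = None,
) -> np.ndarray:
    """Component-wise random-walk MH on beta for all OTUs at once.

    For each covariate p, proposes beta[:, p] + step * eps jointly over the
    J OTUs; the NB likelihood factorizes over OTUs, so acceptance is
    decided per OTU.  ``log_offset`` is the (N, J) log baseline
    ``r + alpha0 + alpha_t``; ``steps`` is the (J, P) matrix of proposal
    scales, adapted in place toward acceptance 0.44 when ``adapt`` is set.
    Returns the (J, P) acceptance indicator of the last sweep.
    """
    J, P = beta.shape
    log_mu = log_offset + X_samples @ beta.T
    loglik = nb_loglik_mu_terms(counts, log_mu, s).sum(axis=0)  # per-OTU
    accepted = np.zeros((J, P), dtype=bool)
    for p in range(P):
        delta = steps[:, p] * rng.standard_normal(J)
        prop = beta[:, p] + delta
        log_mu_prop = log_mu + X_samples[:, [p]] * delta[None, :]
        loglik_prop = nb_loglik_mu_terms(counts, log_mu_prop, s).sum(axis=0)
        sp = sigma2 * phi[:, p]
        log_prior_diff = (beta[:, p] ** 2 - prop**2) / (2.0 * sp)
        log_acc = loglik_prop - loglik + log_prior_diff
        acc = np.log(rng.random(J)) < log_acc
        beta[acc, p] = prop[acc]
        log_mu[:, acc] = log_mu_prop[:, acc]
        loglik[acc] = loglik_prop[acc]
        accepted[:, p] = acc
        if adapt is not None:
            steps[:, p] *= np.exp(adapt * (acc.astype(float) - 0.44))
    return accepted


def update_beta(
    state: RegressionState,
    X_samples: np.ndarray,
    counts_j: np.ndarray,
    log_offset_j: np.ndarray,
    s_j: float,
    j: int,
    rng: np.random.Generator,
    steps_j: np.ndarray | None = None,
    adapt: float | None = None,
) -> RegressionState:
    """MH update of one OTU's coefficient vector (thin single-OTU wrapper
    around :func:`update_beta_block`)."""
    beta_j = state.beta[[j], :]
    steps = np.atleast_2d(steps_j) if steps_j is not None else np.full((1, state.P), 0.1)
    update_beta_block(
        beta_j,
        X_samples,
        counts_j[:, None],
        log_offset_j[:, None],
        np.atleast_1d(s_j),
        state.sigma2[[j]],
        state.phi[[j], :],
        steps,
        rng,
        adapt=adapt,
    )
    state.beta[j] = beta_j[0]
    return state
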