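"""Posterior simulation for the joint negative-binomial model.

The full model for count ``y_{t,k,j}`` of OTU ``j`` in replicate ``k`` at
time ``t`` is

    y_{t,k,j} ~ NB(mu_{t,k,j}, s_j),
    mu_{t,k,j} = exp( r~_{t,k} + a~0_j + a~t_{t,j} + X_t' beta_j ),

with the log sample factors ``r~`` and log OTU factors ``a~0`` under
mean-constrained mixture priors (constraints ``c_r``, ``c_alpha``), the
OTU-time factors under the process-convolution prior, Laplace shrinkage on
``beta``, and Ga(a_s, b_s) on the overdispersions.  Inference is
MH-within-Gibbs: conjugate draws where they exist (shrinkage scales,
mixture labels/weights/means, tau^2), adaptive random-walk Metropolis
elsewhere (beta, theta, r~, a~0, log s), plus a joint shift move
``(r~ + d, a~0 - d)`` that exploits the likelihood's invariance to
improve mixing of the confounded baseline factors, and uniform-prior
imputation of missing categorical covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .constrained_mixture import (
    ConstrainedMixture,
    MixtureAllocation,
    augmented_logpdf,
    gibbs_update,
    hyper_logprior,
    mixture_logpdf,
    sample_prior,
)
from .data_model import CountData, CovariateTable
from .likelihood import nb_logpmf, nb_loglik_mu_terms, sample_nb
from .regression import RegressionState, update_beta_block
from .temporal import ConvolutionBasis, TemporalState, build_basis

__all__ = [
    "MCMCConfig",
    "BaselineState",
    "ModelState",
    "PosteriorDraws",
    "StepSizes",
    "mean_matrix",
    "log_mean_matrix",
    "plugin_size_factors",
    "empirical_constraints",
    "update_overdispersion",
    "joint_update_r_alpha0",
    "impute_missing_covariates",
    "imputation_probabilities",
    "log_joint",
    "init_state",
    "mcmc_step",
    "run_mcmc",
]

_LOG_MU_MAX = 700.0  # exp() overflow guard on the log-mean scale


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class MCMCConfig:
    """Run lengths, hyperparameters and smoothing structure.

    Defaults are the reference analysis settings: 25,000 iterations with
    10,000 burn-in and thinning by 2; Ga(0.5, 0.5) on lambda^2 and
    IG(0.3, 0.3) on sigma^2 for the Laplace prior; mixture priors with
    L_r = 30, L_alpha = 50 components, Dirichlet concentration d = 10,
    Beta(1, 1) sub-weights, omega^2 = 1, v_r^2 = 1, v_alpha^2 = 2;
    Ga(1, 2) on overdispersion; M = 13 basis points with margins
    t1p = t2p = 10 time-units.  ``constraints="auto"`` fixes (c_r,
    c_alpha) empirically at the means of the log classical size-factor
    estimates of the data being fitted.
    """

    iterations: int = 25_000
    burn_in: int = 10_000
    thin: int = 2
    # Laplace / regression hyperparameters
    a_lam: float = 0.5
    b_lam: float = 0.5
    a_sig: float = 0.3
    b_sig: float = 0.3
    # constrained-mixture hyperparameters
    L_r: int = 30
    L_alpha: int = 50
    d: float = 10.0
    a_w: float = 1.0
    b_w: float = 1.0
    omega2: float = 1.0
    v2_r: float = 1.0
    v2_alpha: float = 2.0
    constraints: str | tuple[float, float] = "auto"
    # overdispersion prior
    a_s: float = 1.0
    b_s: float = 2.0
    # temporal process-convolution structure
    M: int = 13
    t1p: float = 10.0
    t2p: float = 10.0
    a_tau: float = 2.0
    b_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "MCMCConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, val in doc.items():
            if isinstance(val, dict):  # allow {mcmc: {...}, hyper: {...}, ...} sections
                flat.update(val)
            else:
                flat[key] = val
        if isinstance(flat.get("constraints"), list):
            flat["constraints"] = tuple(flat["constraints"])
        return cls(**flat)

    @property
    def n_draws(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


# ---------------------------------------------------------------------------
# State containers
# ---------------------------------------------------------------------------

@dataclass
class BaselineState:
    """Baseline-mean factors on the log scale and their priors."""

    r_tilde: np.ndarray  # (N,)
    alpha0_tilde: np.ndarray  # (J,)
    mix_r: ConstrainedMixture
    mix_alpha: ConstrainedMixture
    temporal: TemporalState
    basis: ConvolutionBasis
    alloc_r: MixtureAllocation | None = None
    alloc_alpha: MixtureAllocation | None = None


@dataclass
class ModelState:
    """One complete MCMC state of the model."""

    regression: RegressionState
    baseline: BaselineState
    s: np.ndarray  # (J,) overdispersions
    cat_values: np.ndarray  # (n, P_cat) categorical levels with missing imputed
    a_s: float = 1.0
    b_s: float = 2.0
    log_post: float = np.nan

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s <= 0):
            raise ValueError("overdispersions s must be strictly positive")


@dataclass
class StepSizes:
    """Random-walk proposal scales, adapted during burn-in only."""

    beta: np.ndarray  # (J, P)
    theta: np.ndarray  # (M, J)
    r: np.ndarray  # (N,)
    alpha0: np.ndarray  # (J,)
    log_s: np.ndarray  # (J,)
    joint: float = 0.1

    @classmethod
    def defaults(cls, N: int, J: int, P: int, M: int) -> "StepSizes":
        return cls(
            beta=np.full((J, P), 0.1),
            theta=np.full((M, J), 0.2),
            r=np.full(N, 0.2),
            alpha0=np.full(J, 0.2),
            log_s=np.full(J, 0.4),
        )


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws with derived-quantity accessors."""

    beta: np.ndarray  # (nd, J, P)
    r_tilde: np.ndarray  # (nd, N)
    alpha0_tilde: np.ndarray  # (nd, J)
    theta: np.ndarray  # (nd, M, J)
    tau2: np.ndarray  # (nd, J)
    s: np.ndarray  # (nd, J)
    sigma2: np.ndarray  # (nd, J)
    lambda2: np.ndarray  # (nd, J)
    phi: np.ndarray  # (nd, J, P)
    mix_r_params: np.ndarray  # (nd, 3, L_r): psi, w, eta rows
    mix_alpha_params: np.ndarray  # (nd, 3, L_alpha)
    cat_values: np.ndarray  # (nd, n, P_cat)
    log_post: np.ndarray  # (nd,)
    Z_samples: np.ndarray  # (N, M) kernel weights at sample times
    config: MCMCConfig | None = None
    covariates: CovariateTable | None = None
    basis: ConvolutionBasis | None = None
    seed: int | None = None
    c_r: float = np.nan
    c_alpha: float = np.nan

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def alpha_t(self, d: int) -> np.ndarray:
        """OTU-time factor matrix (N, J) for draw ``d``."""
        return self.Z_samples @ self.theta[d]

    def log_g(self, d: int) -> np.ndarray:
        """Log baseline mean ``r~ + a~0 + a~t`` (N, J) for draw ``d``."""
        return self.r_tilde[d][:, None] + self.alpha0_tilde[d][None, :] + self.alpha_t(d)

    def log_mu(self, d: int, X_samples: np.ndarray) -> np.ndarray:
        """Log mean count (N, J) for draw ``d`` given a sample-level design."""
        return self.log_g(d) + X_samples @ self.beta[d].T

    def design_for_draw(self, d: int, time_index: np.ndarray) -> np.ndarray:
        """Sample-level design matrix using draw ``d``'s imputed covariates."""
        X = self.covariates.design_matrix(self.cat_values[d])
        return X[time_index]

    def posterior_mean_g(self) -> np.ndarray:
        """Posterior mean of the baseline mean count g (N, J), streamed."""
        acc = np.zeros_like(self.log_g(0))
        for d in range(self.n_draws):
            acc += np.exp(self.log_g(d))
        return acc / self.n_draws

    def posterior_mean_mu(self, time_index: np.ndarray) -> np.ndarray:
        """Posterior mean of mu (N, J), using each draw's imputed design."""
        acc = None
        for d in range(self.n_draws):
            mu = np.exp(self.log_mu(d, self.design_for_draw(d, time_index)))
            acc = mu if acc is None else acc + mu
        return acc / self.n_draws

    _BLOCKS = (
        "beta", "r_tilde", "alpha0_tilde", "theta", "tau2", "s",
        "sigma2", "lambda2", "phi", "mix_r_params", "mix_alpha_params",
        "cat_values", "log_post", "Z_samples",
    )

    def save(self, directory) -> None:
        """Write the draws as compressed columnar arrays plus a manifest."""
        import json
        import os
        from dataclasses import asdict

        os.makedirs(directory, exist_ok=True)
        np.savez_compressed(
            os.path.join(directory, "draws.npz"),
            **{name: getattr(self, name) for name in self._BLOCKS},
        )
        manifest = {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "c_r": self.c_r,
            "c_alpha": self.c_alpha,
            "config": asdict(self.config) if self.config else None,
            "blocks": list(self._BLOCKS),
        }
        with open(os.path.join(directory, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        """Read draws written by :meth:`save` (covariates/basis not restored)."""
        import json
        import os

        with np.load(os.path.join(directory, "draws.npz")) as npz:
            blocks = {name: npz[name] for name in cls._BLOCKS}
        with open(os.path.join(directory, "manifest.json")) as fh:
            manifest = json.load(fh)
        cfg = manifest.get("config")
        if cfg is not None:
            if isinstance(cfg.get("constraints"), list):
                cfg["constraints"] = tuple(cfg["constraints"])
            cfg = MCMCConfig(**cfg)
        return cls(
            **blocks, config=cfg, seed=manifest.get("seed"),
            c_r=manifest["c_r"], c_alpha=manifest["c_alpha"],
        )

    def state_at(self, d: int) -> ModelState:
        """Reconstruct the full ModelState of retained draw ``d``."""
        cfg = self.config
        reg = RegressionState(
            self.beta[d].copy(), self.sigma2[d].copy(), self.lambda2[d].copy(),
            self.phi[d].copy(), cfg.a_lam, cfg.b_lam, cfg.a_sig, cfg.b_sig,
        )
        mix_r = ConstrainedMixture(
            *self.mix_r_params[d], v2=cfg.v2_r, c=self.c_r,
            d=cfg.d, a_w=cfg.a_w, b_w=cfg.b_w, omega2=cfg.omega2,
        )
        mix_alpha = ConstrainedMixture(
            *self.mix_alpha_params[d], v2=cfg.v2_alpha, c=self.c_alpha,
            d=cfg.d, a_w=cfg.a_w, b_w=cfg.b_w, omega2=cfg.omega2,
        )
        temporal = TemporalState(
            self.theta[d].copy(), self.tau2[d].copy(), cfg.a_tau, cfg.b_tau
        )
        baseline = BaselineState(
            self.r_tilde[d].copy(), self.alpha0_tilde[d].copy(),
            mix_r, mix_alpha, temporal, self.basis,
        )
        return ModelState(
            reg, baseline, self.s[d].copy(), self.cat_values[d].copy(),
            cfg.a_s, cfg.b_s, self.log_post[d],
        )


# ---------------------------------------------------------------------------
# Deterministic structure
# ---------------------------------------------------------------------------

def _sample_design(state: ModelState, covars: CovariateTable, t_idx: np.ndarray) -> np.ndarray:
    X = covars.design_matrix(state.cat_values)
    return X[t_idx]


def log_mean_matrix(state: ModelState, data: CountData, X_samples: np.ndarray) -> np.ndarray:
    """Log mean counts ``(N, J)``: r~ + a~0 + Z theta + X beta'."""
    bl = state.baseline
    Zs = bl.basis.Z[data.sample_time_index]
    return (
        bl.r_tilde[:, None]
        + bl.alpha0_tilde[None, :]
        + Zs @ bl.temporal.theta
        + X_samples @ state.regression.beta.T
    )


def mean_matrix(state: ModelState, data: CountData, X_samples: np.ndarray) -> np.ndarray:
    """Mean-count matrix ``mu`` (N, J), computed on the log scale."""
    log_mu = log_mean_matrix(state, data, X_samples)
    if np.any(log_mu > _LOG_MU_MAX):
        raise OverflowError("log mean count exceeds 700; state would overflow exp()")
    return np.exp(log_mu)


def plugin_size_factors(data: CountData) -> tuple[np.ndarray, np.ndarray]:
    """Classical plug-in size-factor estimates.

    ``r'_{t,k} = y_{t,k,.} / y_...`` (share of total reads in the sample)
    and ``alpha0'_j = (1/N) sum_samples y_{t,k,j} / r'_{t,k}`` (depth-
    normalized mean abundance of the OTU).
    """
    row_tot = data.counts.sum(axis=1).astype(float)
    r_prime = row_tot / row_tot.sum()
    alpha0_prime = (data.counts / r_prime[:, None]).mean(axis=0)
    return r_prime, alpha0_prime


def empirical_constraints(data: CountData) -> tuple[float, float]:
    """Mean constraints (c_r, c_alpha) from the classical estimates.

    Fixed at the means of the logarithms of ``r'`` and ``alpha0'``.  OTUs
    with all-zero counts give ``alpha0' = 0`` and are excluded from the
    log-mean with a warning (they should have been filtered out anyway).
    """
    r_prime, alpha0_prime = plugin_size_factors(data)
    pos = alpha0_prime > 0
    if not np.all(pos):
        warnings.warn(
            f"{(~pos).sum()} all-zero OTUs excluded from the c_alpha estimate",
            UserWarning,
            stacklevel=2,
        )
    return float(np.mean(np.log(r_prime))), float(np.mean(np.log(alpha0_prime[pos])))


# ---------------------------------------------------------------------------
# Individual updates
# ---------------------------------------------------------------------------

def update_overdispersion(
    state: ModelState,
    data: CountData,
    X_samples: np.ndarray,
    rng: np.random.Generator,
    steps: np.ndarray | None = None,
    adapt: float | None = None,
) -> ModelState:
    """Random-walk MH on log s_j against NB likelihood x Ga(a_s, b_s) prior.

    Vectorized over OTUs: the likelihood factorizes by column, so all J
    proposals are evaluated in one pass.  The log-scale proposal carries a
    Jacobian term ``+log s``.
    """
    if steps is None:
        steps = np.full(state.s.size, 0.4)
    mu = mean_matrix(state, data, X_samples)
    s = state.s
    log_s_prop = np.log(s) + steps * rng.standard_normal(s.size)
    s_prop = np.exp(log_s_prop)
    ll_cur = nb_logpmf(data.counts, mu, s[None, :]).sum(axis=0)
    ll_prop = nb_logpmf(data.counts, mu, s_prop[None, :]).sum(axis=0)
    # Ga(a_s, b_s) prior plus the log-proposal Jacobian
    lp_cur = state.a_s * np.log(s) - state.b_s * s
    lp_prop = state.a_s * np.log(s_prop) - state.b_s * s_prop
    acc = np.log(rng.random(s.size)) < ll_prop - ll_cur + lp_prop - lp_cur
    state.s = np.where(acc, s_prop, s)
    if adapt is not None:
        steps *= np.exp(adapt * (acc.astype(float) - 0.44))
    return state


def _update_r_elementwise(
    state: ModelState, data, X_samples, rng, steps, adapt=None
) -> None:
    bl = state.baseline
    log_mu = log_mean_matrix(state, data, X_samples)
    delta = steps * rng.standard_normal(data.N)
    ll_cur = nb_loglik_mu_terms(data.counts, log_mu, state.s[None, :]).sum(axis=1)
    ll_prop = nb_loglik_mu_terms(
        data.counts, log_mu + delta[:, None], state.s[None, :]
    ).sum(axis=1)
    prior_cur = mixture_logpdf(bl.r_tilde, bl.mix_r)
    prior_prop = mixture_logpdf(bl.r_tilde + delta, bl.mix_r)
    acc = np.log(rng.random(data.N)) < ll_prop - ll_cur + prior_prop - prior_cur
    bl.r_tilde = np.where(acc, bl.r_tilde + delta, bl.r_tilde)
    if adapt is not None:
        steps *= np.exp(adapt * (acc.astype(float) - 0.44))


def _update_alpha0_elementwise(
    state: ModelState, data, X_samples, rng, steps, adapt=None
) -> None:
    bl = state.baseline
    log_mu = log_mean_matrix(state, data, X_samples)
    delta = steps * rng.standard_normal(data.J)
    ll_cur = nb_loglik_mu_terms(data.counts, log_mu, state.s[None, :]).sum(axis=0)
    ll_prop = nb_loglik_mu_terms(
        data.counts, log_mu + delta[None, :], state.s[None, :]
    ).sum(axis=0)
    prior_cur = mixture_logpdf(bl.alpha0_tilde, bl.mix_alpha)
    prior_prop = mixture_logpdf(bl.alpha0_tilde + delta, bl.mix_alpha)
    acc = np.log(rng.random(data.J)) < ll_prop - ll_cur + prior_prop - prior_cur
    bl.alpha0_tilde = np.where(acc, bl.alpha0_tilde + delta, bl.alpha0_tilde)
    if adapt is not None:
        steps *= np.exp(adapt * (acc.astype(float) - 0.44))


def joint_update_r_alpha0(
    state: ModelState,
    rng: np.random.Generator,
    step: float = 0.1,
) -> tuple[ModelState, bool]:
    """Joint shift move ``r~ <- r~ + d``, ``a~0 <- a~0 - d`` (scalar d).

    Every mean count ``mu`` is invariant under the shift, so the
    likelihood term of the acceptance ratio is exactly 1 and acceptance is
    decided by the two constrained-mixture priors alone.  The move lets
    the confounded overall levels of the two factor sets trade off against
    each other, which single-site updates do only by slow diffusion.
    """
    bl = state.baseline
    delta = step * rng.standard_normal()
    log_acc = (
        np.sum(mixture_logpdf(bl.r_tilde + delta, bl.mix_r))
        - np.sum(mixture_logpdf(bl.r_tilde, bl.mix_r))
        + np.sum(mixture_logpdf(bl.alpha0_tilde - delta, bl.mix_alpha))
        - np.sum(mixture_logpdf(bl.alpha0_tilde, bl.mix_alpha))
    )
    accept = np.log(rng.random()) < log_acc
    if accept:
        bl.r_tilde = bl.r_tilde + delta
        bl.alpha0_tilde = bl.alpha0_tilde - delta
    return state, bool(accept)


def _update_theta_block(
    state: ModelState, data, X_samples, rng, steps, adapt=None
) -> None:
    """Per-basis-point MH on theta, vectorized over OTUs (mirrors the
    beta block: likelihood factorizes by OTU column)."""
    bl = state.baseline
    Zs = bl.basis.Z[data.sample_time_index]
    theta, tau2 = bl.temporal.theta, bl.temporal.tau2
    log_mu = log_mean_matrix(state, data, X_samples)
    loglik = nb_loglik_mu_terms(data.counts, log_mu, state.s[None, :]).sum(axis=0)
    for m in range(bl.basis.M):
        delta = steps[m] * rng.standard_normal(data.J)
        prop = theta[m] + delta
        log_mu_prop = log_mu + Zs[:, [m]] * delta[None, :]
        loglik_prop = nb_loglik_mu_terms(
            data.counts, log_mu_prop, state.s[None, :]
        ).sum(axis=0)
        log_prior_diff = (theta[m] ** 2 - prop**2) / (2.0 * tau2)
        acc = np.log(rng.random(data.J)) < loglik_prop - loglik + log_prior_diff
        theta[m, acc] = prop[acc]
        log_mu[:, acc] = log_mu_prop[:, acc]
        loglik[acc] = loglik_prop[acc]
        if adapt is not None:
            steps[m] *= np.exp(adapt * (acc.astype(float) - 0.44))


def _update_tau2(state: ModelState, rng: np.random.Generator) -> None:
    """Conjugate draw: tau2_j | theta ~ IG(a_tau + M/2, b_tau + sum_m theta^2/2)."""
    tmp = state.baseline.temporal
    M = tmp.theta.shape[0]
    shape = tmp.a_tau + 0.5 * M
    scale = tmp.b_tau + 0.5 * np.sum(tmp.theta**2, axis=0)
    tmp.tau2 = scale / rng.gamma(shape, size=tmp.tau2.size)


def imputation_probabilities(
    state: ModelState, data: CountData, covars: CovariateTable, i: int, q: int
) -> np.ndarray:
    """Full-conditional probabilities of the levels of categorical
    covariate ``q`` at time point ``i``.

    Uniform prior over the C levels times the NB likelihood of all OTUs in
    the replicates at that time point; with ``beta`` for the covariate's
    indicator columns at zero, this is exactly uniform.
    """
    C = covars.n_levels[q]
    rows = np.flatnonzero(data.sample_time_index == i)
    cats = state.cat_values.copy()
    loglik = np.empty(C)
    for lev in range(C):
        cats[i, q] = lev
        X = covars.design_matrix(cats)
        log_mu = log_mean_matrix(state, data, X[data.sample_time_index])[rows]
        loglik[lev] = nb_loglik_mu_terms(
            data.counts[rows], log_mu, state.s[None, :]
        ).sum()
    return np.exp(loglik - logsumexp(loglik))


def impute_missing_covariates(
    state: ModelState, data: CountData, covars: CovariateTable, rng: np.random.Generator
) -> ModelState:
    """Gibbs draw of every missing categorical cell from its full
    conditional (uniform prior over levels x NB likelihood)."""
    miss = covars.missing_mask
    for i, q in np.argwhere(miss):
        p = imputation_probabilities(state, data, covars, i, q)
        state.cat_values[i, q] = rng.choice(p.size, p=p)
    return state


# ---------------------------------------------------------------------------
# Joint density (used by correctness tests and the log_post cache)
# ---------------------------------------------------------------------------

def log_joint(
    state: ModelState,
    data: CountData,
    covars: CovariateTable,
    augmented: bool = False,
) -> float:
    """Log joint density of data and parameters at the current state.

    With ``augmented=True`` the mixture priors are evaluated jointly with
    their latent allocation labels; otherwise labels are marginalized.
    Imputed categorical cells contribute their uniform prior mass.
    """
    reg, bl = state.regression, state.baseline
    X_samples = _sample_design(state, covars, data.sample_time_index)
    mu = mean_matrix(state, data, X_samples)
    lp = float(nb_logpmf(data.counts, mu, state.s[None, :]).sum())

    # Laplace scale-mixture prior on beta
    sp = reg.sigma2[:, None] * reg.phi
    lp += float(np.sum(-0.5 * np.log(2 * np.pi * sp) - reg.beta**2 / (2 * sp)))
    half_l2 = reg.lambda2[:, None] / 2.0
    lp += float(np.sum(np.log(half_l2) - half_l2 * reg.phi))
    lp += float(
        np.sum(
            reg.a_lam * np.log(reg.b_lam)
            - gammaln(reg.a_lam)
            + (reg.a_lam - 1) * np.log(reg.lambda2)
            - reg.b_lam * reg.lambda2
        )
    )
    lp += float(
        np.sum(
            reg.a_sig * np.log(reg.b_sig)
            - gammaln(reg.a_sig)
            - (reg.a_sig + 1) * np.log(reg.sigma2)
            - reg.b_sig / reg.sigma2
        )
    )

    # constrained-mixture priors on the baseline factors
    if augmented:
        lp += augmented_logpdf(bl.r_tilde, bl.alloc_r, bl.mix_r)
        lp += augmented_logpdf(bl.alpha0_tilde, bl.alloc_alpha, bl.mix_alpha)
    else:
        lp += float(np.sum(mixture_logpdf(bl.r_tilde, bl.mix_r)))
        lp += float(np.sum(mixture_logpdf(bl.alpha0_tilde, bl.mix_alpha)))
    lp += hyper_logprior(bl.mix_r) + hyper_logprior(bl.mix_alpha)

    # temporal latent weights and variances
    tmp = bl.temporal
    lp += float(
        np.sum(-0.5 * np.log(2 * np.pi * tmp.tau2[None, :]) - tmp.theta**2 / (2 * tmp.tau2[None, :]))
    )
    lp += float(
        np.sum(
            tmp.a_tau * np.log(tmp.b_tau)
            - gammaln(tmp.a_tau)
            - (tmp.a_tau + 1) * np.log(tmp.tau2)
            - tmp.b_tau / tmp.tau2
        )
    )

    # overdispersion prior
    lp += float(
        np.sum(
            state.a_s * np.log(state.b_s)
            - gammaln(state.a_s)
            + (state.a_s - 1) * np.log(state.s)
            - state.b_s * state.s
        )
    )

    # uniform prior over levels for each imputed categorical cell
    for i, q in np.argwhere(covars.missing_mask):
        lp -= np.log(covars.n_levels[q])
    return lp


# ---------------------------------------------------------------------------
# Initialization and the driver
# ---------------------------------------------------------------------------

def init_state(
    data: CountData,
    covars: CovariateTable,
    config: MCMCConfig,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> ModelState:
    """Draw an initial state from the priors.

    Prior draws occasionally land in numerically absurd territory (the
    heavy-tailed shrinkage hyperpriors allow enormous coefficients); a
    rejection guard redraws until the log posterior is finite and the
    largest log mean count is moderate.
    """
    if config.constraints == "auto":
        c_r, c_alpha = empirical_constraints(data)
    else:
        c_r, c_alpha = config.constraints
    basis = build_basis(data.T, config.t1p, config.t2p, config.M, data.time_points)
    n_cat = covars.categorical.shape[1]
    for _ in range(max_tries):
        reg = RegressionState.from_prior(
            data.J, covars.P, rng, config.a_lam, config.b_lam, config.a_sig, config.b_sig
        )
        # The shrinkage hyperpriors are heavy-tailed by design; raw prior
        # draws of sigma^2/phi occasionally produce astronomically large
        # coefficients.  For the starting point only, redraw beta under
        # capped scales (a truncated-prior initialization).
        sig_init = np.minimum(reg.sigma2, 2.0)
        phi_init = np.minimum(reg.phi, 2.0)
        reg.beta = rng.normal(0.0, np.sqrt(sig_init[:, None] * phi_init))
        mix_r = ConstrainedMixture.from_prior(
            config.L_r, c_r, config.v2_r, rng, config.d, config.a_w, config.b_w, config.omega2
        )
        mix_alpha = ConstrainedMixture.from_prior(
            config.L_alpha, c_alpha, config.v2_alpha, rng,
            config.d, config.a_w, config.b_w, config.omega2,
        )
        tau2 = (config.b_tau / rng.gamma(config.a_tau, size=data.J))
        theta = rng.normal(0.0, np.sqrt(tau2)[None, :], size=(config.M, data.J))
        temporal = TemporalState(theta, tau2, config.a_tau, config.b_tau)
        baseline = BaselineState(
            r_tilde=sample_prior(mix_r, data.N, rng),
            alpha0_tilde=sample_prior(mix_alpha, data.J, rng),
            mix_r=mix_r,
            mix_alpha=mix_alpha,
            temporal=temporal,
            basis=basis,
        )
        s = rng.gamma(config.a_s, 1.0 / config.b_s, size=data.J)
        s = np.maximum(s, 1e-8)
        cats = covars.categorical.copy()
        for i, q in np.argwhere(covars.missing_mask):
            cats[i, q] = rng.integers(covars.n_levels[q])
        state = ModelState(reg, baseline, s, cats, config.a_s, config.b_s)
        X_samples = _sample_design(state, covars, data.sample_time_index)
        log_mu = log_mean_matrix(state, data, X_samples)
        if np.max(log_mu) > 30.0:  # e^30 ~ 1e13 counts: absurd, redraw
            continue
        lp = log_joint(state, data, covars)
        if np.isfinite(lp):
            state.log_post = lp
            return state
    raise RuntimeError(
        "could not initialize: log posterior non-finite (or mean counts "
        f"overflowing) after {max_tries} prior draws; check data scaling "
        "and hyperparameters"
    )


def mcmc_step(
    state: ModelState,
    data: CountData,
    covars: CovariateTable,
    steps: StepSizes,
    rng: np.random.Generator,
    adapt: float | None = None,
) -> ModelState:
    """One full MH-within-Gibbs sweep over all parameter blocks.

    Fixed update order: missing-covariate imputation, beta, (phi,
    lambda^2, sigma^2), element-wise r~, element-wise a~0, joint shift
    move, both mixture parameter sweeps, theta, tau^2, s.
    """
    reg, bl = state.regression, state.baseline
    with np.errstate(over="ignore"):
        if covars.missing_mask.any():
            impute_missing_covariates(state, data, covars, rng)
        X_samples = _sample_design(state, covars, data.sample_time_index)

        log_offset = (
            bl.r_tilde[:, None]
            + bl.alpha0_tilde[None, :]
            + bl.basis.Z[data.sample_time_index] @ bl.temporal.theta
        )
        update_beta_block(
            reg.beta, X_samples, data.counts, log_offset, state.s,
            reg.sigma2, reg.phi, steps.beta, rng, adapt=adapt,
        )
        # conjugate shrinkage-scale sweeps (vectorized over OTUs)
        b_abs = np.maximum(np.abs(reg.beta), 1e-10)
        mu_ig = np.sqrt(reg.lambda2[:, None] * reg.sigma2[:, None]) / b_abs
        reg.phi = 1.0 / rng.wald(mu_ig, reg.lambda2[:, None])
        reg.lambda2 = rng.gamma(
            reg.a_lam + reg.P, 1.0 / (reg.b_lam + 0.5 * reg.phi.sum(axis=1))
        )
        reg.sigma2 = (
            reg.b_sig + 0.5 * np.sum(reg.beta**2 / reg.phi, axis=1)
        ) / rng.gamma(reg.a_sig + 0.5 * reg.P, size=reg.J)

        _update_r_elementwise(state, data, X_samples, rng, steps.r, adapt)
        _update_alpha0_elementwise(state, data, X_samples, rng, steps.alpha0, adapt)
        joint_update_r_alpha0(state, rng, steps.joint)

        bl.mix_r, bl.alloc_r = gibbs_update(bl.mix_r, bl.r_tilde, bl.alloc_r, rng, adapt)
        bl.mix_alpha, bl.alloc_alpha = gibbs_update(
            bl.mix_alpha, bl.alpha0_tilde, bl.alloc_alpha, rng, adapt
        )

        _update_theta_block(state, data, X_samples, rng, steps.theta, adapt)
        _update_tau2(state, rng)
        update_overdispersion(state, data, X_samples, rng, steps.log_s, adapt)
    return state


def run_mcmc(
    data: CountData,
    covars: CovariateTable,
    config: MCMCConfig | None = None,
    seed: int | None = None,
    progress: bool = False,
) -> PosteriorDraws:
    """Run the full posterior simulation and return thinned draws.

    Proposal scales follow a Robbins-Monro diminishing-adaptation schedule
    targeting acceptance 0.44 during burn-in and are frozen afterwards, so
    the post-burn-in chain is a fixed Markov kernel with the correct
    stationary law.  Fully reproducible given ``seed``.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(seed)
    state = init_state(data, covars, config, rng)
    steps = StepSizes.defaults(data.N, data.J, covars.P, config.M)

    nd = config.n_draws
    n_cat = covars.categorical.shape[1]
    out = PosteriorDraws(
        beta=np.empty((nd, data.J, covars.P)),
        r_tilde=np.empty((nd, data.N)),
        alpha0_tilde=np.empty((nd, data.J)),
        theta=np.empty((nd, config.M, data.J)),
        tau2=np.empty((nd, data.J)),
        s=np.empty((nd, data.J)),
        sigma2=np.empty((nd, data.J)),
        lambda2=np.empty((nd, data.J)),
        phi=np.empty((nd, data.J, covars.P)),
        mix_r_params=np.empty((nd, 3, config.L_r)),
        mix_alpha_params=np.empty((nd, 3, config.L_alpha)),
        cat_values=np.empty((nd, covars.n, n_cat), dtype=int),
        log_post=np.empty(nd),
        Z_samples=state.baseline.basis.Z[data.sample_time_index],
        config=config,
        covariates=covars,
        basis=state.baseline.basis,
        seed=seed,
        c_r=state.baseline.mix_r.c,
        c_alpha=state.baseline.mix_alpha.c,
    )

    iterator = range(config.iterations)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="mcmc")
    kept = 0
    for it in iterator:
        adapt = min(0.25, 2.0 / (it + 10) ** 0.6) if it < config.burn_in else None
        mcmc_step(state, data, covars, steps, rng, adapt=adapt)
        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0 and kept < nd:
            bl = state.baseline
            out.beta[kept] = state.regression.beta
            out.r_tilde[kept] = bl.r_tilde
            out.alpha0_tilde[kept] = bl.alpha0_tilde
            out.theta[kept] = bl.temporal.theta
            out.tau2[kept] = bl.temporal.tau2
            out.s[kept] = state.s
            out.sigma2[kept] = state.regression.sigma2
            out.lambda2[kept] = state.regression.lambda2
            out.phi[kept] = state.regression.phi
            out.mix_r_params[kept] = [bl.mix_r.psi, bl.mix_r.w, bl.mix_r.eta]
            out.mix_alpha_params[kept] = [
                bl.mix_alpha.psi, bl.mix_alpha.w, bl.mix_alpha.eta
            ]
            out.cat_values[kept] = state.cat_values
            out.log_post[kept] = log_joint(state, data, covars)
            kept += 1
    return out
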