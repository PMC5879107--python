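"""Mean-constrained normal-mixture regularizing prior.

The multiplicative decomposition of the baseline mean count,
``g = r * alpha_0 * alpha_t``, is overparameterized: adding a constant to
the log sample factors and subtracting it from the log OTU factors leaves
``g`` unchanged.  The device that restores identifiability of ``g`` is a
flexible mixture prior whose mean is pinned to a fixed constant ``c``:

    p(x) = sum_l psi_l [ w_l N(x; eta_l, v^2)
                         + (1 - w_l) N(x; (c - w_l eta_l)/(1 - w_l), v^2) ]

Each component is itself a two-normal mixture engineered so that its mean
is exactly ``c`` for any ``(w_l, eta_l)``, hence the prior (and posterior)
mean of the factors is anchored at ``c`` while the shape — skewness,
multimodality, heavy tails — remains free.  The same prior is used for the
log sample size factors (constraint ``c_r``) and the log OTU size factors
(constraint ``c_alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "ConstrainedMixture",
    "MixtureAllocation",
    "mixture_logpdf",
    "sample_prior",
    "sample_allocation",
    "augmented_logpdf",
    "gibbs_update",
]

_W_EPS = 1e-6  # w clipped to [eps, 1-eps]: w in {0,1} degenerates the second sub-mean


@dataclass
class ConstrainedMixture:
    """Parameters and hyperparameters of the constrained mixture prior.

    ``psi`` are the simplex component weights (Dirichlet(d) prior), ``w``
    the within-component sub-weights (Beta(a_w, b_w) prior), ``eta`` the
    free sub-means (N(c, omega2) prior), ``v2`` the common sub-normal
    variance (fixed) and ``c`` the mean constraint.
    """

    psi: np.ndarray
    w: np.ndarray
    eta: np.ndarray
    v2: float
    c: float
    d: float = 10.0
    a_w: float = 1.0
    b_w: float = 1.0
    omega2: float = 1.0
    w_step: np.ndarray | None = field(default=None, repr=False)  # MH logit-scale steps

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        L = self.psi.size
        if not (self.w.size == L and self.eta.size == L):
            raise ValueError("psi, w, eta must have equal length L")
        if abs(self.psi.sum() - 1.0) > 1e-10 or np.any(self.psi <= 0):
            raise ValueError("psi must be a strictly positive simplex vector")
        if np.any(self.w <= 0) or np.any(self.w >= 1):
            raise ValueError("w must lie strictly inside (0, 1)")
        if self.v2 <= 0:
            raise ValueError("v2 must be positive")
        if self.w_step is None:
            self.w_step = np.full(L, 0.5)

    @property
    def L(self) -> int:
        return self.psi.size

    @property
    def second_mean(self) -> np.ndarray:
        """Induced mean of each component's second sub-normal.

        Recomputed from ``(c, w, eta)`` so that the per-component identity
        ``w*eta + (1-w)*second_mean == c`` holds bit-exactly.
        """
        return (self.c - self.w * self.eta) / (1.0 - self.w)

    @classmethod
    def from_prior(
        cls,
        L: int,
        c: float,
        v2: float,
        rng: np.random.Generator,
        d: float = 10.0,
        a_w: float = 1.0,
        b_w: float = 1.0,
        omega2: float = 1.0,
    ) -> "ConstrainedMixture":
        """Draw mixture parameters from their prior (MCMC initialization)."""
        psi = rng.dirichlet(np.full(L, d))
        w = np.clip(rng.beta(a_w, b_w, size=L), _W_EPS, 1 - _W_EPS)
        eta = rng.normal(c, np.sqrt(omega2), size=L)
        return cls(psi, w, eta, v2, c, d=d, a_w=a_w, b_w=b_w, omega2=omega2)


@dataclass
class MixtureAllocation:
    """Latent labels for Gibbs sampling: component ``comp`` in 0..L-1 and
    sub-normal ``sub`` in {0, 1} for each latent unit."""

    comp: np.ndarray
    sub: np.ndarray

    def __post_init__(self) -> None:
        self.comp = np.asarray(self.comp, dtype=int)
        self.sub = np.asarray(self.sub, dtype=int)


def _norm_logpdf(x, mean, v2):
    return -0.5 * np.log(2 * np.pi * v2) - 0.5 * (x - mean) ** 2 / v2


def _cell_logweights(x: np.ndarray, mix: ConstrainedMixture) -> np.ndarray:
    """Log joint weight of each (component, sub-normal) cell, shape (n, 2L)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))[:, None]
    m2 = mix.second_mean
    lw0 = np.log(mix.psi) + np.log(mix.w) + _norm_logpdf(x, mix.eta[None, :], mix.v2)
    lw1 = np.log(mix.psi) + np.log1p(-mix.w) + _norm_logpdf(x, m2[None, :], mix.v2)
    return np.concatenate([lw0, lw1], axis=1)


def mixture_logpdf(x, mix: ConstrainedMixture):
    """Log density of the constrained mixture at ``x`` (scalar or array)."""
    out = logsumexp(_cell_logweights(x, mix), axis=1)
    return float(out[0]) if np.isscalar(x) or np.ndim(x) == 0 else out


def sample_prior(mix: ConstrainedMixture, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` i.i.d. values from the mixture prior."""
    if n < 1:
        raise ValueError("n must be >= 1")
    comp = rng.choice(mix.L, size=n, p=mix.psi)
    sub = (rng.random(n) >= mix.w[comp]).astype(int)
    means = np.where(sub == 0, mix.eta[comp], mix.second_mean[comp])
    return rng.normal(means, np.sqrt(mix.v2))


def sample_allocation(
    values: np.ndarray, mix: ConstrainedMixture, rng: np.random.Generator
) -> MixtureAllocation:
    """Exact conditional draw of (component, sub-normal) labels given values."""
    lw = _cell_logweights(values, mix)
    p = np.exp(lw - logsumexp(lw, axis=1, keepdims=True))
    # inverse-CDF sampling row-wise, vectorized
    cdf = np.cumsum(p, axis=1)
    u = rng.random(p.shape[0])[:, None]
    cell = (u > cdf).sum(axis=1)
    return MixtureAllocation(comp=cell % mix.L, sub=cell // mix.L)


def allocation_probabilities(values: np.ndarray, mix: ConstrainedMixture) -> np.ndarray:
    """Posterior probability of each of the 2L (component, sub) cells,
    shape (n, 2L) with cell index ``sub * L + comp``."""
    lw = _cell_logweights(values, mix)
    return np.exp(lw - logsumexp(lw, axis=1, keepdims=True))


def augmented_logpdf(
    values: np.ndarray, alloc: MixtureAllocation, mix: ConstrainedMixture
) -> float:
    """Log density of (values, labels) under the augmented mixture model."""
    means = np.where(alloc.sub == 0, mix.eta[alloc.comp], mix.second_mean[alloc.comp])
    lw = np.where(alloc.sub == 0, np.log(mix.w[alloc.comp]), np.log1p(-mix.w[alloc.comp]))
    return float(
        np.sum(np.log(mix.psi[alloc.comp]) + lw + _norm_logpdf(values, means, mix.v2))
    )


def hyper_logprior(mix: ConstrainedMixture) -> float:
    """Log prior of (psi, w, eta) under Dirichlet(d) x Beta(a,b) x N(c, omega2)."""
    L, d = mix.L, mix.d
    lp = gammaln(L * d) - L * gammaln(d) + (d - 1) * np.sum(np.log(mix.psi))
    lp += np.sum(
        gammaln(mix.a_w + mix.b_w)
        - gammaln(mix.a_w)
        - gammaln(mix.b_w)
        + (mix.a_w - 1) * np.log(mix.w)
        + (mix.b_w - 1) * np.log1p(-mix.w)
    )
    lp += np.sum(_norm_logpdf(mix.eta, mix.c, mix.omega2))
    return float(lp)


def _update_eta(
    mix: ConstrainedMixture, values: np.ndarray, alloc: MixtureAllocation,
    rng: np.random.Generator,
) -> np.ndarray:
    """Closed-form Gaussian conditional for eta_l.

    Units allocated to sub-normal 0 contribute N(x; eta, v2) terms; units in
    sub-normal 1 contribute through the induced mean
    (c - w*eta)/(1-w) = a*eta + b with a = -w/(1-w), b = c/(1-w), which is
    linear in eta, so the full conditional stays Gaussian.
    """
    eta_new = mix.eta.copy()
    for l in range(mix.L):
        in0 = (alloc.comp == l) & (alloc.sub == 0)
        in1 = (alloc.comp == l) & (alloc.sub == 1)
        a = -mix.w[l] / (1.0 - mix.w[l])
        b = mix.c / (1.0 - mix.w[l])
        prec = 1.0 / mix.omega2 + (in0.sum() + in1.sum() * a * a) / mix.v2
        num = (
            mix.c / mix.omega2
            + values[in0].sum() / mix.v2
            + a * (values[in1] - b).sum() / mix.v2
        )
        eta_new[l] = rng.normal(num / prec, np.sqrt(1.0 / prec))
    return eta_new


def _w_conditional_logpdf(
    w_l: float, l: int, mix: ConstrainedMixture, values: np.ndarray,
    alloc: MixtureAllocation,
) -> float:
    """Unnormalized log conditional of w_l given everything else."""
    in0 = (alloc.comp == l) & (alloc.sub == 0)
    in1 = (alloc.comp == l) & (alloc.sub == 1)
    m2 = (mix.c - w_l * mix.eta[l]) / (1.0 - w_l)
    lp = (mix.a_w - 1) * np.log(w_l) + (mix.b_w - 1) * np.log1p(-w_l)
    lp += in0.sum() * np.log(w_l) + in1.sum() * np.log1p(-w_l)
    lp += float(np.sum(_norm_logpdf(values[in1], m2, mix.v2)))
    return float(lp)


def gibbs_update(
    mix: ConstrainedMixture,
    values: np.ndarray,
    alloc: MixtureAllocation | None,
    rng: np.random.Generator,
    adapt: float | None = None,
) -> tuple[ConstrainedMixture, MixtureAllocation]:
    """One MCMC sweep over the mixture's latent labels and parameters.

    Order: labels (exact multinomial conditional), psi (conjugate
    Dirichlet), eta (conjugate Gaussian, see :func:`_update_eta`), w
    (random-walk Metropolis on logit(w); no conjugate form exists because
    w enters the second sub-mean nonlinearly).  Components with no
    allocated units are refreshed from their prior.  ``adapt``, if given,
    is a Robbins-Monro step factor nudging the w proposal scale toward
    acceptance 0.44 (use only during burn-in).
    """
    values = np.asarray(values, dtype=float)
    alloc = sample_allocation(values, mix, rng)

    counts = np.bincount(alloc.comp, minlength=mix.L)
    psi = rng.dirichlet(mix.d + counts)
    psi = np.clip(psi, 1e-300, None)
    psi = psi / psi.sum()
    mix = replace(mix, psi=psi, w_step=mix.w_step)

    eta = _update_eta(mix, values, alloc, rng)
    # empty components: eta conditional above already reduces to the prior
    mix = replace(mix, eta=eta, w_step=mix.w_step)

    w = mix.w.copy()
    for l in range(mix.L):
        if counts[l] == 0:
            w[l] = np.clip(rng.beta(mix.a_w, mix.b_w), _W_EPS, 1 - _W_EPS)
            continue
        cur = w[l]
        logit = np.log(cur) - np.log1p(-cur)
        prop_logit = logit + mix.w_step[l] * rng.standard_normal()
        prop = np.clip(1.0 / (1.0 + np.exp(-prop_logit)), _W_EPS, 1 - _W_EPS)
        # Jacobian of the logit transform: |dw/dlogit| = w(1-w)
        log_acc = (
            _w_conditional_logpdf(prop, l, mix, values, alloc)
            - _w_conditional_logpdf(cur, l, mix, values, alloc)
            + np.log(prop) + np.log1p(-prop)
            - np.log(cur) - np.log1p(-cur)
        )
        accepted = np.log(rng.random()) < log_acc
        if accepted:
            w[l] = prop
        if adapt is not None:
            mix.w_step[l] = float(
                np.exp(np.log(mix.w_step[l]) + adapt * ((1.0 if accepted else 0.0) - 0.44))
            )
    mix = replace(mix, w=w, w_step=mix.w_step)
    return mix, alloc
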