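"""Synthetic longitudinal OTU datasets with known ground truth.

The generator reproduces the structure of the model's verification study:
sparse covariate effects (a coefficient is zero with probability 0.85,
otherwise drawn near +/-1.5), sample and OTU size factors resampled from
a pool of classical estimates, smooth cosine-plus-quadratic OTU-time
trajectories, Ga(1, 10) overdispersions, and NB counts assembled from the
exact generative mean

    mu^TR = r^TR * alpha0^TR * exp(alpha_t^TR + X' beta^TR).

Two variant trajectory shapes are available for robustness experiments:
i.i.d. normal noise over time (no temporal dependence) and a
discontinuous step-plus-cosine form that violates the smoothness the
process-convolution prior assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CountData, CovariateTable, build_design
from .likelihood import sample_nb

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_beta",
    "simulate_temporal",
    "simulate_size_factors",
    "simulate_covariates",
    "simulate_dataset",
]


@dataclass
class SimTruth:
    """Ground-truth parameter values carried alongside a simulated dataset."""

    beta_true: np.ndarray  # (J, P)
    r_true: np.ndarray  # (N,)
    alpha0_true: np.ndarray  # (J,)
    alpha_t_true: np.ndarray  # (n, J), log scale
    trajectory_params: dict  # a, b, c per OTU plus t_star and times in years
    s_true: np.ndarray  # (J,)
    mu_true: np.ndarray  # (N, J)
    X_true: np.ndarray  # (n, P) complete design (before masking missing cells)
    cat_true: np.ndarray  # (n, P_cat) complete categorical levels

    def g_true(self, time_index: np.ndarray) -> np.ndarray:
        """True baseline mean counts g^TR (N, J)."""
        return (
            self.r_true[:, None]
            * self.alpha0_true[None, :]
            * np.exp(self.alpha_t_true[time_index])
        )


@dataclass
class SimConfig:
    """Dimensions and generative settings of a simulated study.

    The defaults mirror the reference study layout: 200 OTUs observed at
    55 time points spread over roughly 1.6 years with 2-3 replicates per
    time point, six covariates (four continuous, two 2-level indicators),
    sparse effects, and Ga(1, 10) overdispersions (mean 0.1).
    """

    J: int = 200
    n_times: int = 55
    years: float = 1.6
    replicates: tuple[int, ...] = (2, 3)
    P_continuous: int = 4
    categorical_levels: tuple[int, ...] = (2, 2)
    missing_prob: float = 0.0  # fraction of cells of the first categorical set missing
    p_zero: float = 0.85
    effect_mean: float = 1.5
    effect_sd: float = 0.05
    covariate_corr: float = 0.0  # AR(1)-style correlation between continuous covariates
    overdispersion_shape: float = 1.0
    overdispersion_rate: float = 10.0
    temporal: str = "cosine"  # "cosine" | "iid" | "step"
    size_factor_pool: dict | None = None  # {"r": array, "alpha0": array}


def simulate_beta(
    J: int,
    P: int,
    rng: np.random.Generator,
    p_zero: float = 0.85,
    effect_mean: float = 1.5,
    effect_sd: float = 0.05,
) -> np.ndarray:
    """Sparse true coefficients: zero w.p. ``p_zero``, else +/-N(1.5, 0.05^2)
    with equal sign probability."""
    beta = np.zeros((J, P))
    active = rng.random((J, P)) >= p_zero
    sign = np.where(rng.random((J, P)) < 0.5, -1.0, 1.0)
    beta[active] = (sign * rng.normal(effect_mean, effect_sd, size=(J, P)))[active]
    return beta


def _cosine_quadratic(t_years, a, b, c, t_star):
    return a * np.cos(2 * np.pi * (t_years[:, None] - b[None, :])) + c[None, :] * (
        (t_years[:, None] - t_star) ** 2
    )


def simulate_temporal(
    times_in_years: np.ndarray,
    J: int,
    rng: np.random.Generator,
    kind: str = "cosine",
) -> tuple[np.ndarray, dict]:
    """Per-OTU log temporal trajectories evaluated at the time points.

    ``cosine``: a_j cos(2 pi (t - b_j)) + c_j (t - t*)^2 with
    a_j ~ N(0.15, 0.1^2), b_j ~ N(0, 0.5^2), c_j ~ N(0.1, 0.1^2) and t*
    the median observation time — a yearly oscillation with a slow drift,
    different for every OTU.  ``iid``: independent N(0, 0.15^2) noise at
    each time point (no temporal dependence).  ``step``: the cosine form
    plus a +/-0.5 jump at the median time (discontinuous; violates the
    smoothness assumption of the temporal prior).
    """
    t = np.asarray(times_in_years, dtype=float)
    t_star = float(np.median(t))
    a = rng.normal(0.15, 0.1, size=J)
    b = rng.normal(0.0, 0.5, size=J)
    c = rng.normal(0.1, 0.1, size=J)
    params = {"a": a, "b": b, "c": c, "t_star": t_star, "times_years": t, "kind": kind}
    if kind == "cosine":
        alpha = _cosine_quadratic(t, a, b, c, t_star)
    elif kind == "iid":
        alpha = rng.normal(0.0, 0.15, size=(t.size, J))
    elif kind == "step":
        jump = np.where(rng.random(J) < 0.5, -0.5, 0.5)
        alpha = _cosine_quadratic(t, a, b, c, t_star) + jump[None, :] * (
            t[:, None] >= t_star
        )
        params["jump"] = jump
    else:
        raise ValueError(f"unknown temporal kind {kind!r}")
    return alpha, params


def simulate_size_factors(
    pool: dict | None,
    N: int,
    J: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample true size factors, with replacement, from a pool of classical
    estimates (keys ``"r"`` and ``"alpha0"``, e.g. from
    :func:`otubayes.sampler.plugin_size_factors` on any real table).

    Without a pool, a synthetic log-normal stand-in is used: r is a depth
    multiplier centred on 1 with log-sd 0.5 (a few-fold sequencing-depth
    heterogeneity) and alpha0 is log-normal with median ~20 reads and
    log-sd 1.2, so baseline abundances span roughly three orders of
    magnitude around a typical filtered-OTU count.
    """
    if pool is not None:
        r = rng.choice(np.asarray(pool["r"], dtype=float), size=N, replace=True)
        alpha0 = rng.choice(np.asarray(pool["alpha0"], dtype=float), size=J, replace=True)
    else:
        r = np.exp(rng.normal(0.0, 0.5, size=N))
        alpha0 = np.exp(rng.normal(np.log(20.0), 1.2, size=J))
    if np.any(r <= 0) or np.any(alpha0 <= 0):
        raise ValueError("size-factor pools must be strictly positive")
    return r, alpha0


def simulate_covariates(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Raw per-time-point covariates: correlated continuous columns plus
    skewed ordinal columns, with an optional missing mask on the first
    categorical covariate.

    Returns (raw table with missing coded -1, complete categorical matrix,
    time points in the raw table's units).
    """
    n = config.n_times
    times = np.sort(rng.uniform(0.0, config.years, size=n))
    times[0], times[-1] = 0.0, config.years
    cont = rng.standard_normal((n, config.P_continuous))
    rho = config.covariate_corr
    if rho:
        for p in range(1, config.P_continuous):
            cont[:, p] = rho * cont[:, p - 1] + np.sqrt(1 - rho**2) * cont[:, p]
    cats = np.empty((n, len(config.categorical_levels)), dtype=int)
    for q, C in enumerate(config.categorical_levels):
        # right-skewed level frequencies, as for discretized concentrations
        probs = 0.6 ** np.arange(C)
        cats[:, q] = rng.choice(C, size=n, p=probs / probs.sum())
        if np.unique(cats[:, q]).size < 2:  # guarantee two observed levels
            cats[rng.integers(n), q] = 1
    observed = cats.copy()
    if config.missing_prob > 0:
        miss = rng.random(n) < config.missing_prob
        observed[miss, 0] = -1
    raw = pd.DataFrame({"time": times})
    for p in range(config.P_continuous):
        raw[f"x{p + 1}"] = cont[:, p]
    for q in range(cats.shape[1]):
        raw[f"c{q + 1}"] = observed[:, q]
    return raw, cats, times


def simulate_dataset(
    config: SimConfig | None = None,
    seed: int | None = None,
) -> tuple[CountData, CovariateTable, SimTruth]:
    """Generate one complete dataset plus its ground truth.

    Counts are drawn ``y ~ NB(mu^TR, s^TR)`` from the exact generative
    mean; the covariate table handed to the analyst carries the missing
    mask while the truth keeps the complete levels used for generation.
    Setting ``overdispersion_rate = 0`` is not supported; to obtain the
    Poisson limit pass ``overdispersion_shape = 0`` (all ``s = 0``).
    """
    config = config or SimConfig()
    rng = np.random.default_rng(seed)

    raw, cat_true, times = simulate_covariates(config, rng)
    covars = build_design(
        raw, categorical=[f"c{q + 1}" for q in range(len(config.categorical_levels))]
    )
    X_true = covars.design_matrix(cat_true)

    # sample layout: K_i replicates per time point
    K = rng.choice(config.replicates, size=config.n_times)
    t_idx = np.repeat(np.arange(config.n_times), K)
    time_of_sample = times[t_idx]
    rep = np.concatenate([np.arange(1, k + 1) for k in K])
    N = t_idx.size

    beta = simulate_beta(
        config.J, covars.P, rng, config.p_zero, config.effect_mean, config.effect_sd
    )
    # trajectory time scale: convert the observation window to years
    t_years = times * (config.years / max(times[-1], 1e-12)) if times[-1] > 0 else times
    alpha_t, traj = simulate_temporal(t_years, config.J, rng, kind=config.temporal)
    r_true, alpha0_true = simulate_size_factors(
        config.size_factor_pool, N, config.J, rng
    )
    if config.overdispersion_shape == 0:
        s_true = np.zeros(config.J)
    else:
        s_true = rng.gamma(
            config.overdispersion_shape, 1.0 / config.overdispersion_rate, size=config.J
        )

    log_mu = (
        np.log(r_true)[:, None]
        + np.log(alpha0_true)[None, :]
        + alpha_t[t_idx]
        + X_true[t_idx] @ beta.T
    )
    mu = np.exp(log_mu)
    counts = sample_nb(mu, s_true[None, :], rng)
    # an all-zero sample row would degenerate size factors; force one read
    # into the most abundant OTU of any such row (rare at realistic depths)
    zero_rows = counts.sum(axis=1) == 0
    if zero_rows.any():
        counts[zero_rows, np.argmax(mu[zero_rows], axis=1)] = 1

    data = CountData(counts, time_of_sample, rep)
    truth = SimTruth(
        beta_true=beta,
        r_true=r_true,
        alpha0_true=alpha0_true,
        alpha_t_true=alpha_t,
        trajectory_params=traj,
        s_true=s_true,
        mu_true=mu,
        X_true=X_true,
        cat_true=cat_true,
    )
    return data, covars, truth
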