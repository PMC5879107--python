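"""Process-convolution prior for the OTU-time factors.

Temporal dependence in the log baseline abundance of an OTU is modelled by
a Gaussian-process surrogate built by kernel convolution: latent white
noise ``theta_{m,j} ~ N(0, tau_j^2)`` sits at ``M`` fixed basis points
``u_1..u_M`` and a Gaussian kernel ``Z`` smears it over time,

    alpha_tilde_{t,j} = sum_m Z(t - u_m) theta_{m,j}.

The induced process is a zero-mean GP with covariance
``tau_j^2 * Z Z'`` — smooth, cheap (no dense-covariance factorization) and
with all smoothing structure fixed: basis points are evenly spaced over
the margin-extended window ``[-t1p, T + t2p]`` and the kernel range is
tied to the basis resolution, ``gamma^2 = ((2T + t1p + t2p)/M)^2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConvolutionBasis", "TemporalState", "kernel_value", "build_basis", "alpha_tilde"]


@dataclass
class ConvolutionBasis:
    """Fixed smoothing structure: basis locations, kernel range, weights.

    ``Z`` has shape ``(n, M)``: kernel weight of basis point ``m`` at
    observation time ``t_i``.  All entries are strictly positive (the
    Gaussian kernel has full support).
    """

    M: int
    u: np.ndarray
    gamma2: float
    Z: np.ndarray
    t1p: float
    t2p: float
    T: float
    times: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.Z = np.asarray(self.Z, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.u.size != self.M or self.Z.shape != (self.times.size, self.M):
            raise ValueError("inconsistent basis dimensions")
        if np.any(self.Z <= 0):
            raise ValueError("kernel weights must be strictly positive")


@dataclass
class TemporalState:
    """Latent convolution weights and their per-OTU variances.

    ``theta`` is ``(M, J)``; ``tau2[j]`` is the prior variance of column
    ``j`` with conjugate IG(a_tau, b_tau) hyperprior.
    """

    theta: np.ndarray
    tau2: np.ndarray
    a_tau: float = 2.0
    b_tau: float = 1.0

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.tau2 = np.asarray(self.tau2, dtype=float)
        if np.any(self.tau2 <= 0):
            raise ValueError("tau2 must be positive")


def kernel_value(t, u, gamma2: float):
    """Gaussian kernel ``(2 pi gamma^2)^{-1/2} exp(-(t-u)^2 / (2 gamma^2))``."""
    if gamma2 <= 0:
        raise ValueError("gamma2 must be positive")
    t = np.asarray(t, dtype=float)
    u = np.asarray(u, dtype=float)
    out = np.exp(-((t - u) ** 2) / (2.0 * gamma2)) / np.sqrt(2.0 * np.pi * gamma2)
    return float(out) if out.ndim == 0 else out


def build_basis(
    T: float, t1p: float, t2p: float, M: int, times: np.ndarray
) -> ConvolutionBasis:
    """Construct the convolution basis for an observation window ``[0, T]``.

    Basis points are endpoint-inclusive evenly spaced over
    ``[-t1p, T + t2p]`` (the margins stop edge trajectories from being
    pinned toward zero) and the kernel range follows the basis count:
    ``gamma2 = ((2T + t1p + t2p) / M)^2``.  ``M`` should be small enough
    that every kernel overlaps at least one sampled time, else its latent
    weight is informed by nothing but its prior.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if t1p <= 0 or t2p <= 0:
        raise ValueError("margins t1p, t2p must be positive")
    times = np.asarray(times, dtype=float)
    u = -t1p + np.arange(M) * (T + t1p + t2p) / (M - 1)
    gamma2 = ((2.0 * T + t1p + t2p) / M) ** 2
    Z = kernel_value(times[:, None], u[None, :], gamma2)
    return ConvolutionBasis(M=M, u=u, gamma2=gamma2, Z=Z, t1p=t1p, t2p=t2p, T=T, times=times)


def alpha_tilde(basis: ConvolutionBasis, theta_j: np.ndarray) -> np.ndarray:
    """Log OTU-time factor at the observation times: ``Z @ theta_j``.

    Accepts a single ``(M,)`` column or an ``(M, J)`` matrix of latent
    weights; linear in ``theta``.
    """
    theta_j = np.asarray(theta_j, dtype=float)
    return basis.Z @ theta_j
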