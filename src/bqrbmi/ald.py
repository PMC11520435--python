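"""Asymmetric Laplace distribution (ALD) error model for quantile regression.

The tau-th conditional quantile of an outcome is the minimizer of the
asymmetric *check loss*; maximizing an ALD likelihood is equivalent to
minimizing that loss, which is what makes the ALD the working error law of
Bayesian quantile regression.  This module provides the check loss, the ALD
density/CDF/quantile function in its check-loss exponential form, the
constants of the exponential-normal scale mixture

    eps = gamma * l + h * sqrt(l) * m,   l ~ Exp(1),  m ~ N(0, 1),

with gamma = (1 - 2 tau) / (tau (1 - tau)) and h = sqrt(2 / (tau (1 - tau))),
and a sampler that draws from the ALD through that mixture.  Everything else
in the package (the Gibbs sampler, the synthetic-data generator) builds on
these primitives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_TAUS: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.85, 0.95)
"""The six quantile levels the analysis reports by default."""


def _validate_tau(tau: float) -> float:
    tau = float(tau)
    if not 0.0 < tau < 1.0:
        raise ValueError(f"quantile level tau must lie in (0, 1), got {tau}")
    return tau


@dataclass(frozen=True)
class MixtureConstants:
    """Drift and scale of the exponential-normal representation of the ALD."""

    gamma: float
    h: float


@dataclass(frozen=True)
class ALDParams:
    """Location-scale ALD; the tau-quantile of the law equals ``location``."""

    location: float = 0.0
    scale: float = 1.0
    tau: float = 0.5

    def __post_init__(self) -> None:
        _validate_tau(self.tau)
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")


def check_loss(w, tau: float):
    """Asymmetric check loss rho_tau(w) = w (tau - 1{w < 0}).

    Equals ``w * tau`` for w >= 0 and ``w * (tau - 1)`` for w < 0; the
    tau-quantile of a sample minimizes the summed loss.  Vectorized in ``w``.
    """
    tau = _validate_tau(tau)
    w = np.asarray(w, dtype=float)
    out = np.where(w >= 0, w * tau, w * (tau - 1.0))
    return out if out.ndim else float(out)


def mixture_constants(tau: float) -> MixtureConstants:
    """Drift gamma and scale h of the Exp(1)-normal mixture at level tau."""
    tau = _validate_tau(tau)
    denom = tau * (1.0 - tau)
    return MixtureConstants(gamma=(1.0 - 2.0 * tau) / denom, h=float(np.sqrt(2.0 / denom)))


def ald_density(y, params: ALDParams):
    """ALD pdf: tau(1-tau)/scale * exp(-rho_tau((y - location)/scale))."""
    w = (np.asarray(y, dtype=float) - params.location) / params.scale
    out = params.tau * (1.0 - params.tau) / params.scale * np.exp(-check_loss(w, params.tau))
    return out if out.ndim else float(out)


def ald_cdf(y, params: ALDParams):
    """Closed-form piecewise-exponential ALD distribution function."""
    tau = params.tau
    w = (np.asarray(y, dtype=float) - params.location) / params.scale
    lower = tau * np.exp((1.0 - tau) * w)
    upper = 1.0 - (1.0 - tau) * np.exp(-tau * w)
    out = np.where(w < 0, lower, upper)
    return out if out.ndim else float(out)


def ald_ppf(q, params: ALDParams):
    """Inverse of :func:`ald_cdf`; defined for q in (0, 1)."""
    tau = params.tau
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    lower = np.log(q / tau) / (1.0 - tau)
    upper = -np.log((1.0 - q) / (1.0 - tau)) / tau
    w = np.where(q < tau, lower, upper)
    out = params.location + params.scale * w
    return out if out.ndim else float(out)


def sample_ald_via_mixture(n: int, params: ALDParams, seed: int) -> np.ndarray:
    """Draw n ALD variates through the exponential-normal mixture.

    Reproducible for a fixed integer seed.  The standardized draws have mean
    gamma (since E[Exp(1)] = 1) and empirical tau-quantile converging to 0.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 draws, got {n}")
    const = mixture_constants(params.tau)
    rng = np.random.default_rng(seed)
    latent = rng.exponential(1.0, size=n)
    normal = rng.standard_normal(n)
    eps = const.gamma * latent + const.h * np.sqrt(latent) * normal
    return params.location + params.scale * eps


def sample_ald_inverse_cdf(n: int, params: ALDParams, seed: int) -> np.ndarray:
    """Independent ALD sampler by inversion of the closed-form CDF.

    Serves as the cross-check route against the mixture sampler.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 draws, got {n}")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    u = np.clip(u, 1e-15, 1.0 - 1e-15)
    return ald_ppf(u, params)
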