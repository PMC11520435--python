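"""Gibbs sampler for Bayesian quantile regression under the ALD likelihood.

The model for quantile level tau is

    y_i = x_i' beta(tau) + eps_i,   eps_i ~ ALD(tau),

written through the exponential-normal mixture as

    y_i | l_i ~ N(x_i' beta + gamma l_i, h^2 l_i),   l_i ~ Exp(1).

With a multivariate-normal prior on beta the two full conditionals are exact:
beta | y, l is Gaussian with precision  Omega0^-1 + sum_i x_i x_i' / (h^2 l_i)
and the latent l_i | y, beta is GIG(1/2, delta_i, phi) with
delta_i = |y_i - x_i' beta| / h and phi^2 = gamma^2 / h^2 + 2.  The sampler
alternates the two blocks, discards a burn-in and keeps every thin-th draw.

The error scale is fixed at 1 by default (the mixture above carries no free
scale).  An optional extension places an inverse-gamma prior on a scale
sigma and adds it as a third Gibbs block; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize

from .ald import _validate_tau, check_loss, mixture_constants
from .gig import GIGParams, sample_gig_half

RESIDUAL_FLOOR = 1e-10
"""Absolute residuals below this are floored before forming the GIG
parameters: a = 0 makes the order-1/2 GIG draw improper."""


@dataclass
class EncodedDataset:
    """Outcome vector plus full-rank design matrix with a leading intercept."""

    outcome: np.ndarray
    design: np.ndarray
    column_labels: list[str]

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        n, p = self.design.shape
        if self.outcome.shape != (n,):
            raise ValueError("outcome length must match design rows")
        if len(self.column_labels) != p:
            raise ValueError("need one label per design column")
        if not (np.all(np.isfinite(self.outcome)) and np.all(np.isfinite(self.design))):
            raise ValueError("dataset contains missing or non-finite values")
        if not np.allclose(self.design[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        if n <= p:
            raise ValueError(f"need more observations than coefficients (n={n}, p={p})")
        if np.linalg.matrix_rank(self.design) < p:
            raise ValueError("design matrix is rank deficient")

    @property
    def n(self) -> int:
        return self.design.shape[0]

    @property
    def p(self) -> int:
        return self.design.shape[1]


@dataclass
class PriorSpec:
    """Multivariate-normal prior beta ~ N(beta_mean, beta_cov)."""

    beta_mean: np.ndarray
    beta_cov: np.ndarray

    def __post_init__(self) -> None:
        self.beta_mean = np.asarray(self.beta_mean, dtype=float)
        self.beta_cov = np.asarray(self.beta_cov, dtype=float)
        p = self.beta_mean.shape[0]
        if self.beta_cov.shape != (p, p):
            raise ValueError("beta_cov must be p x p")
        if not np.allclose(self.beta_cov, self.beta_cov.T):
            raise ValueError("beta_cov must be symmetric")
        try:
            linalg.cholesky(self.beta_cov, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("beta_cov must be positive definite") from exc

    @classmethod
    def diffuse(cls, p: int, variance: float = 100.0) -> "PriorSpec":
        """Zero-mean prior with covariance ``variance * I`` (the default)."""
        return cls(np.zeros(p), variance * np.eye(p))


@dataclass
class SamplerConfig:
    """MCMC schedule: 10,000 iterations, 1,000 burn-in, thin 5 by default."""

    iterations: int = 10_000
    burn_in: int = 1_000
    thin: int = 5
    seed: int = 0
    estimate_scale: bool = False
    scale_prior_shape: float = 0.01
    scale_prior_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thin


@dataclass
class PosteriorChain:
    """Retained post-burn-in, thinned coefficient draws for one tau."""

    tau: float
    draws: np.ndarray
    column_labels: list[str]
    latent_last: np.ndarray
    scale_draws: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]

    def to_csv(self, path) -> None:
        """One row per retained draw, one column per coefficient."""
        import pandas as pd

        pd.DataFrame(self.draws, columns=self.column_labels).to_csv(path, index=False)


def beta_full_conditional(
    data: EncodedDataset,
    latents: np.ndarray,
    tau: float,
    prior: PriorSpec,
    scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the Gaussian full conditional of beta.

    Precision = Omega0^-1 + X' diag(1/(h^2 sigma l)) X and
    mean = Cov (Omega0^-1 beta0 + X' (y - gamma l)/(h^2 sigma l)).
    """
    latents = np.asarray(latents, dtype=float)
    if np.any(latents <= 0):
        raise ValueError("latent mixing variables must be strictly positive")
    mean, chol = _beta_conditional_factors(data, latents, tau, _prior_factors(prior), scale)
    eye = np.eye(data.p)
    cov = linalg.cho_solve((chol, True), eye)
    cov = 0.5 * (cov + cov.T)
    return mean, cov


def _prior_factors(prior: PriorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Prior precision matrix and precision-weighted prior mean."""
    prec = linalg.cho_solve((linalg.cholesky(prior.beta_cov, lower=True), True),
                            np.eye(prior.beta_mean.shape[0]))
    prec = 0.5 * (prec + prec.T)
    return prec, prec @ prior.beta_mean


def _beta_conditional_factors(data, latents, tau, prior_factors, scale):
    """Return (conditional mean, lower Cholesky factor of the precision)."""
    const = mixture_constants(tau)
    prior_prec, prior_rhs = prior_factors
    w = 1.0 / (const.h**2 * scale * latents)
    xw = data.design * w[:, None]
    precision = prior_prec + data.design.T @ xw
    rhs = prior_rhs + xw.T @ (data.outcome - const.gamma * latents)
    try:
        chol = linalg.cholesky(precision, lower=True)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular precision matrix in the coefficient full conditional; "
            "check the design for collinearity"
        ) from exc
    mean = linalg.cho_solve((chol, True), rhs)
    return mean, chol


def latent_full_conditional(
    residual: float, tau: float, floor: float = RESIDUAL_FLOOR
) -> GIGParams:
    """GIG(1/2, |residual|/h, sqrt(gamma^2/h^2 + 2)) full conditional of one latent."""
    const = mixture_constants(tau)
    a = max(abs(float(residual)), floor) / const.h
    b = float(np.sqrt(const.gamma**2 / const.h**2 + 2.0))
    return GIGParams(order=0.5, a=a, b=b)


def run_gibbs(
    data: EncodedDataset,
    tau: float,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorChain:
    """Run the two-block (optionally three-block) Gibbs sampler at level tau.

    Coefficients start at the least-squares solution and latents at 1; the
    chain is deterministic given ``config.seed``.  Retained draws exclude the
    burn-in and keep every ``thin``-th iteration thereafter, giving exactly
    ``(iterations - burn_in) // thin`` rows (1800 under the defaults).
    """
    tau = _validate_tau(tau)
    prior = prior if prior is not None else PriorSpec.diffuse(data.p)
    config = config if config is not None else SamplerConfig()
    if prior.beta_mean.shape[0] != data.p:
        raise ValueError("prior dimension does not match design")

    rng = np.random.default_rng(config.seed)
    const = mixture_constants(tau)
    prior_factors = _prior_factors(prior)

    beta = np.linalg.lstsq(data.design, data.outcome, rcond=None)[0]
    latents = np.ones(data.n)
    sigma = 1.0

    retained = np.empty((config.n_retained, data.p))
    sigma_trace = np.empty(config.n_retained) if config.estimate_scale else None
    keep = 0
    for it in range(1, config.iterations + 1):
        mean, chol = _beta_conditional_factors(data, latents, tau, prior_factors, sigma)
        z = rng.standard_normal(data.p)
        beta = mean + linalg.solve_triangular(chol.T, z, lower=False)

        resid = data.outcome - data.design @ beta
        a_vec = np.maximum(np.abs(resid), RESIDUAL_FLOOR) / (const.h * np.sqrt(sigma))
        b_lat = np.sqrt((const.gamma**2 / const.h**2 + 2.0) / sigma)
        latents = sample_gig_half(data.n, a_vec, b_lat, rng)

        if config.estimate_scale:
            sq = (resid - const.gamma * latents) ** 2 / (2.0 * const.h**2 * latents)
            shape = config.scale_prior_shape + 1.5 * data.n
            rate = config.scale_prior_rate + float(np.sum(sq) + np.sum(latents))
            sigma = 1.0 / rng.gamma(shape, 1.0 / rate)

        if not np.all(np.isfinite(beta)):
            raise RuntimeError(f"non-finite coefficient draw at iteration {it}")
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            retained[keep] = beta
            if sigma_trace is not None:
                sigma_trace[keep] = sigma
            keep += 1

    return PosteriorChain(
        tau=tau,
        draws=retained[:keep],
        column_labels=list(data.column_labels),
        latent_last=latents,
        scale_draws=sigma_trace[:keep] if sigma_trace is not None else None,
    )


def derive_tau_seed(master_seed: int, index: int) -> int:
    """Deterministic per-quantile seed: SeedSequence([master, index]) state word."""
    return int(np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0] % (2**31))


def fit_multi_quantile(
    data: EncodedDataset,
    taus: Sequence[float],
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> dict[float, PosteriorChain]:
    """One independent chain per quantile level, seeded from the master seed."""
    taus = [(_validate_tau(t)) for t in taus]
    if len(set(taus)) != len(taus):
        raise ValueError("quantile levels must be distinct")
    config = config if config is not None else SamplerConfig()
    chains: dict[float, PosteriorChain] = {}
    for i, tau in enumerate(taus):
        cfg = SamplerConfig(
            iterations=config.iterations,
            burn_in=config.burn_in,
            thin=config.thin,
            seed=derive_tau_seed(config.seed, i),
            estimate_scale=config.estimate_scale,
            scale_prior_shape=config.scale_prior_shape,
            scale_prior_rate=config.scale_prior_rate,
        )
        chains[tau] = run_gibbs(data, tau, prior, cfg)
    return chains


def check_loss_objective(beta: np.ndarray, data: EncodedDataset, tau: float) -> float:
    """Summed check loss of the residuals y - X beta at level tau."""
    resid = data.outcome - data.design @ np.asarray(beta, dtype=float)
    return float(np.sum(check_loss(resid, tau)))


def check_loss_minimizer(data: EncodedDataset, tau: float) -> np.ndarray:
    """Frequentist quantile-regression fit by direct numerical minimization.

    Minimizes the (non-differentiable) summed check loss with a derivative-free
    Powell search started at the least-squares solution.  Used as the
    independent cross-check for the posterior means of the Gibbs sampler.
    """
    tau = _validate_tau(tau)
    best = np.linalg.lstsq(data.design, data.outcome, rcond=None)[0]
    best_f = check_loss_objective(best, data, tau)
    # restart Powell from its own solution until the objective stops moving;
    # the loss is piecewise linear, so a single pass can stall on a ridge
    for _ in range(8):
        res = optimize.minimize(
            check_loss_objective,
            best,
            args=(data, tau),
            method="Powell",
            options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 10_000},
        )
        if res.fun >= best_f - 1e-12:
            best = np.asarray(res.x, dtype=float)
            break
        best, best_f = np.asarray(res.x, dtype=float), float(res.fun)
    return best
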