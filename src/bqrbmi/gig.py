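"""Generalized inverse Gaussian (GIG) density and order-1/2 sampler.

In the ALD Gibbs sampler each latent mixing variable has a GIG full
conditional at order nu = 1/2, with density

    f(x | nu, a, b) = (b/a)^nu / (2 K_nu(ab)) * x^(nu-1)
                      * exp(-(a^2 / x + b^2 x) / 2),   x > 0,

where K_nu is the modified Bessel function of the third kind.  Only the
order-1/2 sampler is needed: if Y follows an inverse Gaussian law with mean
b/a and shape b^2 (which is GIG(-1/2, b, a)), then 1/Y is GIG(1/2, a, b).
The inverse Gaussian draw itself uses numpy's transformation-with-root-
selection generator, so the scheme is exact and rejection-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special


@dataclass(frozen=True)
class GIGParams:
    """Order nu and positive parameters (a, b) of the GIG law."""

    order: float
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(f"GIG parameters a, b must be positive, got a={self.a}, b={self.b}")


def gig_density(x, params: GIGParams):
    """Normalized GIG pdf; returns 0 for x <= 0."""
    x = np.asarray(x, dtype=float)
    nu, a, b = params.order, params.a, params.b
    norm = (b / a) ** nu / (2.0 * special.kv(nu, a * b))
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = norm * x ** (nu - 1.0) * np.exp(-0.5 * (a**2 / x + b**2 * x))
    out = np.where(x > 0, dens, 0.0)
    return out if out.ndim else float(out)


def gig_half_mean(a: float, b: float) -> float:
    """E[X] for X ~ GIG(1/2, a, b): (a/b) K_{3/2}(ab)/K_{1/2}(ab) = a/b + 1/b^2."""
    return a / b + 1.0 / b**2


def sample_gig_half(n: int, a, b, seed=None) -> np.ndarray:
    """Draw n variates from GIG(1/2, a, b) for positive a, b.

    ``a`` may be a vector (one draw per element, as the Gibbs sweep needs);
    ``seed`` may be an integer or an existing :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise ValueError(f"need n >= 1 draws, got {n}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("GIG parameters a, b must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # 1/X ~ inverse Gaussian(mean=b/a, shape=b^2) when X ~ GIG(1/2, a, b)
    inv = rng.wald(b / a, b**2, size=n)
    return 1.0 / inv
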