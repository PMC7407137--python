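"""Closed-form log-densities of the flow model's building blocks.

The observation family is the negative binomial in its mean/overdispersion
parameterization::

    log NegBin(y | mu, phi) = lgamma(y + phi) - lgamma(phi) - lgamma(y + 1)
                              + phi * log(phi / (phi + mu))
                              + y * log(mu / (phi + mu))

with Var(Y) = mu + mu^2 / phi, so phi -> infinity recovers the Poisson.
Latent transitions use the location-scale Student-t. Priors are the weakly
informative set used for inference: 1/phi ~ HalfCauchy(0,5),
sigma ~ HalfCauchy(0,5), nu ~ Gamma(2, 0.1) (shape/rate), rho ~ Normal(0,1),
lambda_1 ~ Cauchy(0,5).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "negbin_logpmf",
    "student_t_logpdf",
    "halfcauchy_logpdf",
    "cauchy_logpdf",
    "gamma_logpdf",
    "normal_logpdf",
]

_LOG_2_OVER_PI = np.log(2.0 / np.pi)


def negbin_logpmf(y, mu, phi):
    """Negative-binomial log-pmf, mean ``mu`` and overdispersion ``phi``.

    Broadcasts over array arguments. ``y`` must be a non-negative integer,
    ``mu > 0``, ``phi > 0``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer")
    if np.any(mu <= 0) or np.any(phi <= 0):
        raise ValueError("mu and phi must be positive")
    out = (
        gammaln(y + phi)
        - gammaln(phi)
        - gammaln(y + 1)
        + phi * np.log(phi / (phi + mu))
        + y * np.log(mu / (phi + mu))
    )
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("non-finite negative-binomial log-pmf")
    return out if out.ndim else float(out)


def student_t_logpdf(x, loc, scale, nu):
    """Location-scale Student-t log-density."""
    x = np.asarray(x, dtype=float)
    if np.any(np.asarray(scale) <= 0) or np.any(np.asarray(nu) <= 0):
        raise ValueError("scale and nu must be positive")
    z = (x - loc) / scale
    out = (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(nu * np.pi)
        - np.log(scale)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )
    return out if np.ndim(out) else float(out)


def halfcauchy_logpdf(x, scale=5.0):
    """Half-Cauchy(0, scale) log-density on x > 0."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        _LOG_2_OVER_PI - np.log(scale) - np.log1p((x / scale) ** 2),
        -np.inf,
    )
    return out if out.ndim else float(out)


def cauchy_logpdf(x, loc=0.0, scale=5.0):
    x = np.asarray(x, dtype=float)
    out = -np.log(np.pi * scale) - np.log1p(((x - loc) / scale) ** 2)
    return out if out.ndim else float(out)


def gamma_logpdf(x, shape=2.0, rate=0.1):
    """Gamma log-density in the shape/rate convention."""
    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * np.log(np.where(x > 0, x, 1.0)) - rate * x,
        -np.inf,
    )
    return out if out.ndim else float(out)


def normal_logpdf(x, loc=0.0, scale=1.0):
    x = np.asarray(x, dtype=float)
    z = (x - loc) / scale
    out = -0.5 * np.log(2.0 * np.pi) - np.log(scale) - 0.5 * z * z
    return out if out.ndim else float(out)
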