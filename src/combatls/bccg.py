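"""Box-Cox Cole-Green (LMS) distribution: density, CDF, quantiles, sampling.

A positive variable ``y`` follows BCCG(mu, sigma, nu) when

    z = ((y/mu)**nu - 1) / (nu * sigma)    for nu != 0
    z = log(y/mu) / sigma                  for nu == 0

is standard normal.  ``mu`` is the median, ``sigma`` the (approximate)
coefficient of variation, and ``nu`` the Box-Cox power controlling skewness.
As is conventional for growth-chart work, the small truncation mass below
y = 0 (present when nu > 0) is ignored; :func:`truncation_mass` quantifies it.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

_NU_EPS = 1e-12


def _validate(mu, sigma) -> None:
    if np.any(np.asarray(mu) <= 0):
        raise ValueError("mu must be positive")
    if np.any(np.asarray(sigma) <= 0):
        raise ValueError("sigma must be positive")


def bccg_z(y, mu, sigma, nu):
    """Box-Cox transform to the standard-normal scale."""
    _validate(mu, sigma)
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    t = np.log(y / np.asarray(mu, dtype=float))
    nu_arr = np.asarray(nu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    safe_nu = np.where(np.abs(nu_arr) < _NU_EPS, 1.0, nu_arr)
    z_gen = np.expm1(nu_arr * t) / (safe_nu * sigma)
    z_log = t / sigma
    return np.where(np.abs(nu_arr) < _NU_EPS, z_log, z_gen)


def bccg_cdf(y, mu, sigma, nu):
    """P(Y <= y) under BCCG(mu, sigma, nu), truncation ignored."""
    return ndtr(bccg_z(y, mu, sigma, nu))


def bccg_quantile(q, mu, sigma, nu):
    """Inverse CDF.  ``q`` must lie strictly in (0, 1).

    For nu > 0, quantiles below the (ignored) truncation mass have no
    positive preimage; the Box-Cox argument is clamped at a tiny positive
    value there, mapping them to essentially zero.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("q must be strictly inside (0, 1)")
    _validate(mu, sigma)
    zq = ndtri(q)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu_arr = np.asarray(nu, dtype=float)
    safe_nu = np.where(np.abs(nu_arr) < _NU_EPS, 1.0, nu_arr)
    arg = np.maximum(1.0 + nu_arr * sigma * zq, 1e-15)
    with np.errstate(invalid="ignore"):
        y_gen = mu * arg ** (1.0 / safe_nu)
    y_log = mu * np.exp(sigma * zq)
    return np.where(np.abs(nu_arr) < _NU_EPS, y_log, y_gen)


def bccg_logpdf(y, mu, sigma, nu):
    """Log density (truncation-mass normalization ignored)."""
    z = bccg_z(y, mu, sigma, nu)
    y = np.asarray(y, dtype=float)
    nu_arr = np.asarray(nu, dtype=float)
    return (
        (nu_arr - 1.0) * np.log(y)
        - nu_arr * np.log(np.asarray(mu, dtype=float))
        - np.log(np.asarray(sigma, dtype=float))
        - 0.5 * z**2
        - 0.5 * np.log(2.0 * np.pi)
    )


def bccg_rvs(mu, sigma, nu, size=None, rng=None):
    """Draw samples by pushing standard-normal draws through the quantile map."""
    rng = np.random.default_rng(rng)
    if size is None:
        size = np.broadcast_shapes(np.shape(mu), np.shape(sigma), np.shape(nu))
    u = rng.uniform(1e-12, 1 - 1e-12, size=size)
    return bccg_quantile(u, mu, sigma, nu)


def bccg_mean_var(mu, sigma, nu):
    """Approximate mean and variance (second-order expansion in sigma).

    Exact for nu = 1 where Y = mu * (1 + sigma * Z):
    mean = mu, var = (mu * sigma)**2.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    mean = mu * (1.0 + 0.5 * sigma**2 * (1.0 - nu))
    var = (mu * sigma) ** 2
    return mean, var


def truncation_mass(mu, sigma, nu):
    """Probability mass the untruncated model places below y = 0 (nu > 0 only)."""
    nu = np.asarray(nu, dtype=float)
    with np.errstate(divide="ignore"):
        mass = ndtr(-1.0 / (np.abs(nu) * np.asarray(sigma, dtype=float)))
    return np.where(nu > 0, mass, 0.0)
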