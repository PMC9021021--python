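"""Generalized gamma distribution kernel.

Three-parameter positive-valued family used as the outcome distribution of
the normative charts.  Parameterization::

    theta = 1 / (sigma**2 * nu**2),   z = (y / mu)**nu
    f(y)  = |nu| * theta**theta * z**theta * exp(-theta * z) / (Gamma(theta) * y)

so that ``mu`` is a natural-scale location (scale) parameter, ``sigma`` a
dimensionless relative-scale parameter and ``nu`` a real shape/skewness
parameter.  Special cases:

* ``nu = 1``  -> gamma distribution with shape ``1/sigma**2`` and mean ``mu``;
* ``nu -> 0`` -> log-normal with log-mean ``log(mu)`` and log-SD ``sigma``;
* ``nu < 0``  -> the transform ``y -> z`` is decreasing, handled via the
  upper regularized incomplete gamma so the CDF stays proper.

Below ``|nu| < NU_EPS`` every operation switches to the log-normal limiting
form (``theta`` diverges as ``nu -> 0``).  All functions broadcast over
numpy arrays; the dataclass :class:`GGParams` carries a validated scalar
parameter triple.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy import stats

__all__ = [
    "GGParams",
    "NU_EPS",
    "gg_logpdf",
    "gg_pdf",
    "gg_cdf",
    "gg_quantile",
    "gg_sample",
    "gg_mean",
    "gg_sd",
]

#: below this |nu| the log-normal limiting form is used everywhere
NU_EPS = 1e-5


@dataclass(frozen=True)
class GGParams:
    """Parameter triple (mu, sigma, nu) of the generalized gamma.

    mu : positive location, in phenotype units (e.g. mm^3)
    sigma : positive relative scale, dimensionless
    nu : real shape; |nu| < NU_EPS means the log-normal limit
    """

    mu: float
    sigma: float
    nu: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu) or self.mu <= 0:
            raise ValueError(f"mu must be a positive finite real, got {self.mu!r}")
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"sigma must be a positive finite real, got {self.sigma!r}")
        if not np.isfinite(self.nu):
            raise ValueError(f"nu must be a finite real, got {self.nu!r}")


def _as_arrays(y, params):
    if params is not None:
        mu, sigma, nu = params.mu, params.sigma, params.nu
    else:
        raise TypeError("params is required")
    return np.asarray(y, dtype=float), mu, sigma, nu


def _check_y_positive(y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("y must be positive and finite (field: y)")
    return y


def _check_params_arrays(mu, sigma, nu):
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(~np.isfinite(mu)) or np.any(mu <= 0):
        raise ValueError("mu must be positive and finite (field: mu)")
    if np.any(~np.isfinite(sigma)) or np.any(sigma <= 0):
        raise ValueError("sigma must be positive and finite (field: sigma)")
    if np.any(~np.isfinite(nu)):
        raise ValueError("nu must be finite (field: nu)")
    return mu, sigma, nu


def logpdf_arrays(y, mu, sigma, nu):
    """Vectorized log-density; broadcasts all arguments."""
    y = _check_y_positive(y)
    mu, sigma, nu = _check_params_arrays(mu, sigma, nu)
    y, mu, sigma, nu = np.broadcast_arrays(y, mu, sigma, nu)
    out = np.empty(y.shape, dtype=float)
    ln_mask = np.abs(nu) < NU_EPS
    if np.any(ln_mask):
        r = np.log(y[ln_mask]) - np.log(mu[ln_mask])
        s = sigma[ln_mask]
        out[ln_mask] = (
            -np.log(y[ln_mask]) - np.log(s) - 0.5 * np.log(2 * np.pi)
            - 0.5 * (r / s) ** 2
        )
    gg = ~ln_mask
    if np.any(gg):
        yv, mv, sv, nv = y[gg], mu[gg], sigma[gg], nu[gg]
        theta = 1.0 / (sv * sv * nv * nv)
        u = nv * (np.log(yv) - np.log(mv))
        # log f = log|nu| + theta*(log theta + u - e^u) - lgamma(theta) - log y
        out[gg] = (
            np.log(np.abs(nv))
            + theta * (np.log(theta) + u - np.exp(u))
            - special.gammaln(theta)
            - np.log(yv)
        )
    return out if out.shape else float(out)


def cdf_arrays(y, mu, sigma, nu):
    """Vectorized CDF; broadcasts all arguments."""
    y = _check_y_positive(y)
    mu, sigma, nu = _check_params_arrays(mu, sigma, nu)
    y, mu, sigma, nu = np.broadcast_arrays(y, mu, sigma, nu)
    out = np.empty(y.shape, dtype=float)
    ln_mask = np.abs(nu) < NU_EPS
    if np.any(ln_mask):
        r = (np.log(y[ln_mask]) - np.log(mu[ln_mask])) / sigma[ln_mask]
        out[ln_mask] = special.ndtr(r)
    gg = ~ln_mask
    if np.any(gg):
        yv, mv, sv, nv = y[gg], mu[gg], sigma[gg], nu[gg]
        theta = 1.0 / (sv * sv * nv * nv)
        z = np.exp(nv * (np.log(yv) - np.log(mv)))
        lower = special.gammainc(theta, theta * z)
        upper = special.gammaincc(theta, theta * z)
        out[gg] = np.where(nv > 0, lower, upper)
    return out if out.shape else float(out)


def quantile_arrays(p, mu, sigma, nu):
    """Vectorized quantile function; broadcasts all arguments."""
    p = np.asarray(p, dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie in the open interval (0, 1) (field: p)")
    mu, sigma, nu = _check_params_arrays(mu, sigma, nu)
    p, mu, sigma, nu = np.broadcast_arrays(p, mu, sigma, nu)
    out = np.empty(p.shape, dtype=float)
    ln_mask = np.abs(nu) < NU_EPS
    if np.any(ln_mask):
        out[ln_mask] = np.exp(
            np.log(mu[ln_mask]) + sigma[ln_mask] * special.ndtri(p[ln_mask])
        )
    gg = ~ln_mask
    if np.any(gg):
        pv, mv, sv, nv = p[gg], mu[gg], sigma[gg], nu[gg]
        theta = 1.0 / (sv * sv * nv * nv)
        g = np.where(
            nv > 0,
            special.gammaincinv(theta, pv),
            special.gammainccinv(theta, pv),
        )
        out[gg] = mv * np.exp(np.log(g / theta) / nv)
    return out if out.shape else float(out)


def moments_arrays(mu, sigma, nu):
    """Mean and SD of the distribution; NaN where the moment is undefined.

    E[y^k] = mu^k * theta^(-k/nu) * Gamma(theta + k/nu) / Gamma(theta),
    defined only when theta + k/nu > 0 (always true for nu > 0).
    """
    mu, sigma, nu = _check_params_arrays(mu, sigma, nu)
    mu, sigma, nu = np.broadcast_arrays(np.asarray(mu, float), sigma, nu)
    mean = np.full(mu.shape, np.nan)
    sd = np.full(mu.shape, np.nan)
    ln_mask = np.abs(nu) < NU_EPS
    if np.any(ln_mask):
        s2 = sigma[ln_mask] ** 2
        m = mu[ln_mask] * np.exp(s2 / 2.0)
        mean[ln_mask] = m
        sd[ln_mask] = m * np.sqrt(np.expm1(s2))
    gg = ~ln_mask
    if np.any(gg):
        mv, sv, nv = mu[gg], sigma[gg], nu[gg]
        theta = 1.0 / (sv * sv * nv * nv)
        with np.errstate(invalid="ignore"):
            ok1 = theta + 1.0 / nv > 0
            ok2 = theta + 2.0 / nv > 0
            lg = special.gammaln(theta)
            m1 = np.where(
                ok1,
                np.exp(
                    np.log(mv)
                    - np.log(theta) / nv
                    + special.gammaln(np.where(ok1, theta + 1.0 / nv, 1.0))
                    - lg
                ),
                np.nan,
            )
            m2 = np.where(
                ok2,
                np.exp(
                    2 * np.log(mv)
                    - 2 * np.log(theta) / nv
                    + special.gammaln(np.where(ok2, theta + 2.0 / nv, 1.0))
                    - lg
                ),
                np.nan,
            )
        mean[gg] = m1
        with np.errstate(invalid="ignore"):
            var = m2 - m1 ** 2
            sd[gg] = np.where(var >= 0, np.sqrt(np.maximum(var, 0.0)), np.nan)
    if mean.shape:
        return mean, sd
    return float(mean), float(sd)


# ---------------------------------------------------------------------------
# public scalar-params API


def gg_logpdf(y, params: GGParams):
    """Log-density of the generalized gamma at ``y > 0``."""
    return logpdf_arrays(y, params.mu, params.sigma, params.nu)


def gg_pdf(y, params: GGParams):
    return np.exp(gg_logpdf(y, params))


def gg_cdf(y, params: GGParams):
    """CDF at ``y > 0``; lies in [0, 1] and is non-decreasing in ``y``."""
    return cdf_arrays(y, params.mu, params.sigma, params.nu)


def gg_quantile(p, params: GGParams):
    """Quantile function for ``p`` in the open interval (0, 1)."""
    return quantile_arrays(p, params.mu, params.sigma, params.nu)


def gg_mean(params: GGParams):
    return moments_arrays(params.mu, params.sigma, params.nu)[0]


def gg_sd(params: GGParams):
    """Standard deviation; NaN when the second moment is undefined (nu < 0
    with theta + 2/nu <= 0)."""
    return moments_arrays(params.mu, params.sigma, params.nu)[1]


def gg_sample(n: int, params: GGParams, seed) -> np.ndarray:
    """Draw ``n`` reproducible variates via inverse-CDF of counter-based
    uniforms (Philox), so identical seeds give identical vectors on any
    platform."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.Generator(np.random.Philox(seed))
    u = rng.random(int(n))
    # keep u strictly inside (0,1)
    u = np.clip(u, 1e-16, 1 - 1e-16)
    return quantile_arrays(u, params.mu, params.sigma, params.nu)


def sample_arrays(mu, sigma, nu, rng) -> np.ndarray:
    """Inverse-CDF sampling with per-element parameters (one draw each)."""
    mu = np.asarray(mu, dtype=float)
    u = rng.random(np.broadcast(mu, sigma, nu).shape)
    u = np.clip(u, 1e-16, 1 - 1e-16)
    return quantile_arrays(u, mu, sigma, nu)


def gg_frozen(params: GGParams):
    """scipy frozen distribution equivalent (for cross-checks): gengamma.

    scipy's ``gengamma(a, c, scale)`` has density proportional to
    x^(c*a-1) exp(-x^c); our family maps to a=theta, c=nu,
    scale = mu * theta**(-1/nu) for nu != 0.
    """
    if abs(params.nu) < NU_EPS:
        return stats.lognorm(s=params.sigma, scale=params.mu)
    theta = 1.0 / (params.sigma ** 2 * params.nu ** 2)
    scale = params.mu * theta ** (-1.0 / params.nu)
    return stats.gengamma(a=theta, c=params.nu, scale=scale)
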