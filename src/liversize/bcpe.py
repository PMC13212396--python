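"""Box-Cox Power Exponential (BCPE) distribution.

The BCPE family underlies LMS-type centile estimation: a positive response
``y`` is mapped through a Box-Cox transform to an (approximately) standard
power-exponential variable,

    z = ((y/mu)**nu - 1) / (nu * sigma)      for nu != 0
    z = log(y/mu) / sigma                    for nu == 0,

where ``mu > 0`` is the median (location), ``sigma > 0`` the approximate
coefficient of variation, ``nu`` the skewness-correcting Box-Cox power, and
``tau > 0`` the power-exponential tail-heaviness. ``tau = 2`` gives the
Box-Cox normal (LMS) family, and additionally ``nu = 1`` the ordinary normal
with mean ``mu`` and standard deviation ``mu * sigma``.

The standardized kernel is the unit-variance power exponential

    f_Z(z) = tau * exp(-0.5 * |z/c|**tau) / (c * 2**(1 + 1/tau) * Gamma(1/tau))

with ``c**2 = 2**(-2/tau) * Gamma(1/tau) / Gamma(3/tau)``. For ``nu > 0``
the transform only reaches ``z > -1/(sigma*nu)`` (positivity of ``y``); the
implied truncation mass is ignored while it is below ``TRUNC_TOL`` and the
distribution is renormalized on the truncated support otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "BCPEParams",
    "bc_transform",
    "bc_inverse",
    "bcpe_logpdf",
    "bcpe_pdf",
    "bcpe_cdf",
    "bcpe_quantile",
    "bcpe_sample",
    "pe_scale_c",
    "pe_cdf",
    "pe_quantile",
]

#: below this absolute value nu is treated as exactly zero (log transform)
NU_EPS = 1e-9
#: truncation mass below which the Box-Cox support cut is ignored
TRUNC_TOL = 1e-6


@dataclass(frozen=True)
class BCPEParams:
    """Parameters of one BCPE law: location, spread, skewness, tail power."""

    mu: float
    sigma: float
    nu: float
    tau: float = 2.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive and finite, got {self.sigma}")
        if not np.isfinite(self.nu):
            raise ValueError(f"nu must be finite, got {self.nu}")
        if not (np.isfinite(self.tau) and self.tau > 0):
            raise ValueError(f"tau must be positive and finite, got {self.tau}")


def pe_scale_c(tau):
    """Scale constant c of the unit-variance power-exponential kernel."""
    tau = np.asarray(tau, dtype=float)
    log_c2 = (-2.0 / tau) * np.log(2.0) + special.gammaln(1.0 / tau) - special.gammaln(3.0 / tau)
    return np.exp(0.5 * log_c2)


def pe_logpdf(z, tau):
    """Log density of the standardized (unit-variance) power exponential."""
    z = np.asarray(z, dtype=float)
    c = pe_scale_c(tau)
    return (
        np.log(tau)
        - 0.5 * np.abs(z / c) ** tau
        - np.log(c)
        - (1.0 + 1.0 / tau) * np.log(2.0)
        - special.gammaln(1.0 / tau)
    )


def pe_cdf(z, tau):
    """CDF of the standardized power exponential via the regularized lower
    incomplete gamma function."""
    z = np.asarray(z, dtype=float)
    c = pe_scale_c(tau)
    s = 0.5 * np.abs(z / c) ** tau
    core = special.gammainc(1.0 / tau, s)
    return 0.5 * (1.0 + np.sign(z) * core)


def pe_quantile(p, tau):
    """Quantile function of the standardized power exponential."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    c = pe_scale_c(tau)
    u = 2.0 * p - 1.0
    s = special.gammaincinv(1.0 / tau, np.abs(u))
    return np.sign(u) * c * (2.0 * s) ** (1.0 / tau)


def bc_transform(y, params: BCPEParams):
    """Box-Cox transform of ``y`` to the standardized scale z.

    Continuous in nu at 0 (log form used when ``|nu| < NU_EPS``).
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    mu, sigma, nu = params.mu, params.sigma, params.nu
    if abs(nu) < NU_EPS:
        return np.log(y / mu) / sigma
    return ((y / mu) ** nu - 1.0) / (nu * sigma)


def bc_inverse(z, params: BCPEParams):
    """Inverse Box-Cox transform: z back to the measurement scale (cm)."""
    z = np.asarray(z, dtype=float)
    mu, sigma, nu = params.mu, params.sigma, params.nu
    if abs(nu) < NU_EPS:
        return mu * np.exp(sigma * z)
    base = 1.0 + sigma * nu * z
    if np.any(base <= 0):
        raise ValueError("quantile outside Box-Cox support")
    return mu * base ** (1.0 / nu)


def _trunc_masses(params: BCPEParams) -> tuple[float, float]:
    """Probability mass of Z lost below/above the Box-Cox support edge.

    Returns (lower_mass, upper_mass); at most one is nonzero. Masses below
    TRUNC_TOL are reported as 0 (ignored downstream).
    """
    nu, sigma, tau = params.nu, params.sigma, params.tau
    if abs(nu) < NU_EPS:
        return 0.0, 0.0
    edge = -1.0 / (sigma * nu)
    if nu > 0:
        m = float(pe_cdf(edge, tau))
        return (m, 0.0) if m > TRUNC_TOL else (0.0, 0.0)
    m = float(1.0 - pe_cdf(edge, tau))
    return (0.0, m) if m > TRUNC_TOL else (0.0, 0.0)


def bcpe_logpdf(y, params: BCPEParams):
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    mu, sigma, nu, tau = params.mu, params.sigma, params.nu, params.tau
    z = bc_transform(y, params)
    logf = (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma) + pe_logpdf(z, tau)
    lo, hi = _trunc_masses(params)
    if lo or hi:
        logf = logf - np.log1p(-(lo + hi))
    return logf


def bcpe_pdf(y, params: BCPEParams):
    """BCPE density (per cm)."""
    return np.exp(bcpe_logpdf(y, params))


def bcpe_cdf(y, params: BCPEParams):
    """BCPE distribution function, strictly increasing in y."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive")
    z = bc_transform(y, params)
    F = pe_cdf(z, params.tau)
    lo, hi = _trunc_masses(params)
    if lo or hi:
        F = np.clip((F - lo) / (1.0 - lo - hi), 0.0, 1.0)
    return F


def bcpe_quantile(p, params: BCPEParams):
    """BCPE quantile function; p = 0.5 returns mu exactly."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    lo, hi = _trunc_masses(params)
    if lo or hi:
        p = lo + p * (1.0 - lo - hi)
    z = pe_quantile(p, params.tau)
    return bc_inverse(z, params)


# ---------------------------------------------------------------------------
# vectorized kernels with per-observation parameters (used by the fitter and
# the residual diagnostics; tau is scalar there)


def _z_arrays(y, mu, sigma, nu):
    y, mu, sigma, nu = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (y, mu, sigma, nu))
    )
    small = np.abs(nu) < NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    ratio = y / mu
    z_bc = (ratio ** nu_safe - 1.0) / (nu_safe * sigma)
    z_log = np.log(ratio) / sigma
    return np.where(small, z_log, z_bc)


def _trunc_mass_arrays(sigma, nu, tau):
    """Per-observation (lower, upper) truncation masses, zeroed when below
    TRUNC_TOL."""
    sigma, nu = np.broadcast_arrays(
        np.asarray(sigma, dtype=float), np.asarray(nu, dtype=float)
    )
    lo = np.zeros(sigma.shape)
    hi = np.zeros(sigma.shape)
    pos = nu >= NU_EPS
    neg = nu <= -NU_EPS
    if np.any(pos):
        lo[pos] = pe_cdf(-1.0 / (sigma[pos] * nu[pos]), tau)
    if np.any(neg):
        hi[neg] = 1.0 - pe_cdf(-1.0 / (sigma[neg] * nu[neg]), tau)
    lo[lo <= TRUNC_TOL] = 0.0
    hi[hi <= TRUNC_TOL] = 0.0
    return lo, hi


def logpdf_arrays(y, mu, sigma, nu, tau):
    """BCPE log density with array-valued (mu, sigma, nu) and scalar tau."""
    y, mu, sigma, nu = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (y, mu, sigma, nu))
    )
    z = _z_arrays(y, mu, sigma, nu)
    out = (nu - 1.0) * np.log(y) - nu * np.log(mu) - np.log(sigma) + pe_logpdf(z, tau)
    lo, hi = _trunc_mass_arrays(sigma, nu, tau)
    mass = lo + hi
    if np.any(mass > 0):
        out = out - np.log1p(-mass)
    return out


def cdf_arrays(y, mu, sigma, nu, tau):
    """BCPE CDF with array-valued (mu, sigma, nu) and scalar tau."""
    z = _z_arrays(y, mu, sigma, nu)
    F = pe_cdf(z, tau)
    lo, hi = _trunc_mass_arrays(sigma, nu, tau)
    mass = lo + hi
    if np.any(mass > 0):
        F = np.clip((F - lo) / (1.0 - mass), 0.0, 1.0)
    return F


def quantile_arrays(p, mu, sigma, nu, tau):
    """BCPE quantiles with array-valued (p, mu, sigma, nu) and scalar tau."""
    p, mu, sigma, nu = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (p, mu, sigma, nu))
    )
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("p must lie strictly inside (0, 1)")
    lo, hi = _trunc_mass_arrays(sigma, nu, tau)
    mass = lo + hi
    p_eff = np.where(mass > 0, lo + p * (1.0 - mass), p)
    z = pe_quantile(p_eff, tau)
    small = np.abs(nu) < NU_EPS
    nu_safe = np.where(small, 1.0, nu)
    base = 1.0 + sigma * nu_safe * z
    if np.any(base[~small] <= 0):
        raise ValueError("quantile outside Box-Cox support")
    y_bc = mu * np.maximum(base, 1e-300) ** (1.0 / nu_safe)
    y_log = mu * np.exp(sigma * z)
    return np.where(small, y_log, y_bc)


def bcpe_sample(n: int, params: BCPEParams, seed=None):
    """Draw ``n`` values by inverse-transform sampling (reproducible by seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(0.0, 1.0, size=n)
    # keep u strictly interior so the quantile stays finite
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    return bcpe_quantile(u, params)
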