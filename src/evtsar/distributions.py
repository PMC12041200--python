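"""Distance distributions and extreme-value laws for nested species sampling.

A species whose individuals are spread around a range centre according to an
isotropic bivariate normal kernel has individual-to-focal-point distances that
follow a Rice distribution with location ``upsilon`` (distance of the range
centre to the focal point) and scale ``sigma`` (the kernel scale).  When the
range is centred on the focal point the Rice law reduces exactly to a Rayleigh
law.  The first individual of a species encountered while expanding a circle
around the focal point is the one at the *minimum* distance, so the species'
entry into a species-area curve is governed by the distribution of the minimum
of ``n`` draws from its parent distance distribution,

    L(r) = 1 - (1 - F(r))**n,

and, for large ``n``, by the generalised extreme value (GEV) family for
minima with location ``mu``, scale ``sigma_gev`` and shape ``xi``.

Conventions
-----------
The GEV for minima is implemented by reflection: if ``M`` is a minimum then
``-M`` follows the ordinary GEV for maxima.  With this convention ``xi = -0.5``
is the Weibull-type law obtained for minima of distances bounded below (range
covering the focal point) and ``xi = 0`` the Gumbel-type limit reached when
the parent distance distribution is approximately normal (range far from the
focal point).  scipy's ``genextreme`` shape ``c`` equals ``-xi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "RiceParams",
    "RayleighParams",
    "RiceMoments",
    "MinimaLaw",
    "GEVMinParams",
    "GEVMinFit",
    "GEVFitError",
    "rice_pdf",
    "rice_cdf",
    "rice_rvs",
    "rice_moments",
    "rayleigh_pdf",
    "rayleigh_cdf",
    "marcum_q1",
    "minima_cdf",
    "minima_pdf",
    "area_from_radius",
    "radius_from_area",
    "gev_min_cdf",
    "gev_min_pdf",
    "gev_min_rvs",
    "fit_gev_min",
]

RAYLEIGH_MEAN_SD_RATIO = np.sqrt(np.pi / (4.0 - np.pi))


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RiceParams:
    """Rice distance distribution: centre at distance ``upsilon``, kernel scale ``sigma``."""

    upsilon: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.upsilon >= 0:
            raise ValueError(f"upsilon must be >= 0, got {self.upsilon}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def ratio(self) -> float:
        """Centre distance in units of kernel scale (the phase diagnostic)."""
        return self.upsilon / self.sigma


@dataclass(frozen=True)
class RayleighParams:
    """Rayleigh distance distribution (range centred on the focal point)."""

    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")


@dataclass(frozen=True)
class RiceMoments:
    mean: float
    variance: float

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))


@dataclass(frozen=True)
class GEVMinParams:
    """GEV-for-minima parameters (see module docstring for the sign convention)."""

    mu: float
    sigma_gev: float
    xi: float

    def __post_init__(self) -> None:
        if not self.sigma_gev > 0:
            raise ValueError(f"sigma_gev must be > 0, got {self.sigma_gev}")


@dataclass(frozen=True)
class GEVMinFit:
    params: GEVMinParams
    loglik: float
    converged: bool
    n_obs: int


class GEVFitError(RuntimeError):
    """Raised when maximum-likelihood GEV estimation fails."""


# --------------------------------------------------------------------------
# Rice / Rayleigh
# --------------------------------------------------------------------------

def _check_r(r):
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    return r


def rice_pdf(r, p: RiceParams):
    """Rice probability density of the distance to the focal point.

    Evaluated as ``r/sigma**2 * exp(-(r - upsilon)**2 / (2 sigma**2)) * i0e(r
    upsilon / sigma**2)`` where ``i0e`` is the exponentially scaled modified
    Bessel function, which keeps the product finite for large
    ``r*upsilon/sigma**2``.
    """
    r = _check_r(r)
    s2 = p.sigma**2
    out = (r / s2) * np.exp(-((r - p.upsilon) ** 2) / (2.0 * s2)) * special.i0e(r * p.upsilon / s2)
    return out if out.ndim else float(out)


def marcum_q1(a: float, b) -> np.ndarray:
    """Marcum Q-function of order 1 via the noncentral chi-square survival function.

    ``Q1(a, b) = P(X > b**2)`` with ``X ~ chi2(df=2, nc=a**2)`` (exact identity).
    """
    b = np.asarray(b, dtype=float)
    return stats.ncx2.sf(b**2, df=2, nc=a**2)


def rice_cdf(r, p: RiceParams):
    """Rice cumulative distribution, ``1 - Q1(upsilon/sigma, r/sigma)``."""
    r = _check_r(r)
    out = 1.0 - marcum_q1(p.upsilon / p.sigma, r / p.sigma)
    return out if out.ndim else float(out)


def rice_rvs(p: RiceParams, size, rng: np.random.Generator):
    """Sample distances: Euclidean norm of an isotropic normal displaced by ``upsilon``."""
    x = rng.normal(p.upsilon, p.sigma, size=size)
    y = rng.normal(0.0, p.sigma, size=size)
    return np.hypot(x, y)


def rice_moments(p: RiceParams) -> RiceMoments:
    """Exact mean and variance of the Rice law.

    mean = sigma * sqrt(pi/2) * 1F1(-1/2; 1; -upsilon**2 / (2 sigma**2)),
    variance = 2 sigma**2 + upsilon**2 - mean**2.
    """
    z = -(p.upsilon**2) / (2.0 * p.sigma**2)
    h = special.hyp1f1(-0.5, 1.0, z)
    if not np.isfinite(h):
        raise ArithmeticError(f"hyp1f1(-0.5, 1, {z}) failed for {p}")
    mean = p.sigma * np.sqrt(np.pi / 2.0) * h
    variance = 2.0 * p.sigma**2 + p.upsilon**2 - mean**2
    return RiceMoments(mean=float(mean), variance=float(variance))


def rayleigh_pdf(r, p: RayleighParams):
    r = _check_r(r)
    s2 = p.sigma**2
    out = (r / s2) * np.exp(-(r**2) / (2.0 * s2))
    return out if out.ndim else float(out)


def rayleigh_cdf(r, p: RayleighParams):
    r = _check_r(r)
    out = -np.expm1(-(r**2) / (2.0 * p.sigma**2))
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# distribution of the minimum (Eq. for L and the area scale)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MinimaLaw:
    """Law of the minimum of ``n`` i.i.d. draws from a parent distance distribution.

    ``parent_cdf`` maps distance r >= 0 to probability; ``parent_pdf`` is
    optional and enables the analytic density.  The minimum's cdf is
    ``L(r) = 1 - (1 - F(r))**n``.
    """

    parent_cdf: Callable[[np.ndarray], np.ndarray]
    n: int
    parent_pdf: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    def cdf(self, r):
        return minima_cdf(self, r)

    def cdf_area(self, area):
        return minima_cdf(self, radius_from_area(area))

    def pdf(self, r):
        return minima_pdf(self, r)

    def pdf_area(self, area):
        """Density of the minimum on the area scale (dA = 2 pi r dr)."""
        area = np.asarray(area, dtype=float)
        r = radius_from_area(area)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, minima_pdf(self, r) / (2.0 * np.pi * r), 0.0)
        return out if out.ndim else float(out)


def minima_cdf(law: MinimaLaw, r):
    """cdf of the minimum: ``1 - (1 - F(r))**n``, computed via log1p/expm1."""
    F = np.asarray(law.parent_cdf(np.asarray(r, dtype=float)), dtype=float)
    F = np.clip(F, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        out = -np.expm1(law.n * np.log1p(-F))
    out = np.where(F >= 1.0, 1.0, out)
    return out if out.ndim else float(out)


def minima_pdf(law: MinimaLaw, r):
    """Density of the minimum, ``n (1 - F)**(n-1) f`` (requires ``parent_pdf``)."""
    if law.parent_pdf is None:
        raise ValueError("MinimaLaw.parent_pdf is required for the analytic density")
    r = np.asarray(r, dtype=float)
    F = np.clip(np.asarray(law.parent_cdf(r), dtype=float), 0.0, 1.0)
    f = np.asarray(law.parent_pdf(r), dtype=float)
    with np.errstate(divide="ignore"):
        out = law.n * np.exp((law.n - 1) * np.log1p(-F)) * f
    out = np.where(F >= 1.0, 0.0, out)
    return out if out.ndim else float(out)


def area_from_radius(r):
    """Area of the circle of radius r around the focal point, ``A = pi r**2``."""
    r = _check_r(r)
    out = np.pi * r**2
    return out if out.ndim else float(out)


def radius_from_area(area):
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("areas must be non-negative")
    out = np.sqrt(area / np.pi)
    return out if out.ndim else float(out)


# --------------------------------------------------------------------------
# GEV for minima
# --------------------------------------------------------------------------

def _reflect(p: GEVMinParams) -> tuple[float, float, float]:
    # scipy genextreme (maxima) parameters of -M: c = -xi, loc = -mu
    return -p.xi, -p.mu, p.sigma_gev


def gev_min_cdf(x, p: GEVMinParams):
    """cdf of the GEV for minima; outside the support it saturates at 0 or 1."""
    c, loc, scale = _reflect(p)
    out = stats.genextreme.sf(-np.asarray(x, dtype=float), c, loc=loc, scale=scale)
    return out if out.ndim else float(out)


def gev_min_pdf(x, p: GEVMinParams):
    c, loc, scale = _reflect(p)
    out = stats.genextreme.pdf(-np.asarray(x, dtype=float), c, loc=loc, scale=scale)
    return out if out.ndim else float(out)


def gev_min_rvs(p: GEVMinParams, size, rng: np.random.Generator):
    c, loc, scale = _reflect(p)
    return -stats.genextreme.rvs(c, loc=loc, scale=scale, size=size, random_state=rng)


# ---- maximum-likelihood fitting ------------------------------------------

def _sample_lmoments3(x: np.ndarray) -> tuple[float, float, float]:
    """First three sample L-moments (unbiased probability-weighted moments)."""
    x = np.sort(x)
    n = len(x)
    i = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum((i - 1) / (n - 1) * x) / n
    b2 = np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * x) / n
    return b0, 2 * b1 - b0, 6 * b2 - 6 * b1 + b0


def _gev_lmoment_start(z: np.ndarray) -> tuple[float, float, float]:
    """Hosking's L-moment estimates for the GEV (maxima) as optimiser start."""
    l1, l2, l3 = _sample_lmoments3(z)
    t3 = l3 / l2
    c = 2.0 / (3.0 + t3) - np.log(2.0) / np.log(3.0)
    k = 7.8590 * c + 2.9554 * c**2  # Hosking k = -xi
    if abs(k) < 1e-8:
        k = 1e-8
    g = special.gamma(1.0 + k)
    alpha = l2 * k / ((1.0 - 2.0 ** (-k)) * g)
    loc = l1 - alpha * (1.0 - g) / k
    return loc, alpha, -k


def _gev_max_negloglik(z: np.ndarray, loc: float, log_scale: float, xi: float) -> float:
    """Negative log-likelihood of the GEV for maxima, vectorised by hand."""
    scale = np.exp(log_scale)
    s = (z - loc) / scale
    if abs(xi) < 1e-9:
        return float(len(z) * log_scale + np.sum(s + np.exp(-s)))
    t = 1.0 + xi * s
    if np.any(t <= 0):
        return np.inf
    logt = np.log(t)
    return float(len(z) * log_scale + (1.0 + 1.0 / xi) * np.sum(logt) + np.sum(np.exp(-logt / xi)))


def fit_gev_min(
    minima: Sequence[float],
    xi_bounds: tuple[float, float] = (-1.0, 1.0),
) -> GEVMinFit:
    """Fit the GEV for minima by maximum likelihood.

    The sample of minima is negated and fitted as GEV-for-maxima with the
    shape bounded to ``xi_bounds`` (minima of distances bounded below sit near
    the ``xi = -0.5`` region where unbounded MLE can run away).  Optimisation
    starts from Hosking's L-moment estimates and retries from
    ``xi0 in {-0.5, 0}``; an L-BFGS-B pass is polished with Nelder-Mead.

    Raises
    ------
    GEVFitError
        If the sample is degenerate or no start converges.
    """
    m = np.asarray(minima, dtype=float)
    if m.ndim != 1 or len(m) < 30:
        raise GEVFitError(f"need a 1-d sample of >= 30 minima, got shape {m.shape}")
    if not np.all(np.isfinite(m)):
        raise GEVFitError("sample contains non-finite values")
    if np.ptp(m) == 0:
        raise GEVFitError("degenerate (constant) sample")

    z = -m  # maxima convention
    loc0, a0, xi0 = _gev_lmoment_start(z)
    if not (np.isfinite(loc0) and np.isfinite(a0) and a0 > 0):
        loc0, a0, xi0 = float(z.mean()), float(z.std() or 1.0), 0.0
    log_a0 = np.log(max(a0, 1e-300))
    lo, hi = xi_bounds
    starts = [
        (loc0, log_a0, float(np.clip(xi0, lo + 0.01, hi - 0.01))),
        (loc0, log_a0, -0.5),
        (loc0, log_a0, 0.0),
    ]

    def nll(p):
        return _gev_max_negloglik(z, p[0], p[1], p[2])

    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for s in starts:
            r = optimize.minimize(
                nll, s, method="L-BFGS-B",
                bounds=[(None, None), (None, None), xi_bounds],
                options=dict(ftol=1e-14, gtol=1e-12),
            )
            r2 = optimize.minimize(
                nll, r.x if np.isfinite(r.fun) else s, method="Nelder-Mead",
                options=dict(xatol=1e-10, fatol=1e-10, maxiter=2000),
            )
            cand = r2 if r2.fun <= r.fun else r
            if np.isfinite(cand.fun) and (best is None or cand.fun < best.fun):
                best = cand

    if best is None:
        raise GEVFitError("GEV MLE failed to converge from all starting points")
    loc, log_scale, xi = best.x
    params = GEVMinParams(mu=-float(loc), sigma_gev=float(np.exp(log_scale)),
                          xi=float(np.clip(xi, lo, hi)))
    return GEVMinFit(params=params, loglik=-float(best.fun), converged=bool(best.success),
                     n_obs=len(m))
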