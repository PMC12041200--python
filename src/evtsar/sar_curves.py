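"""Species-area curves: assembly from minima, the mixture law, and phase slopes.

A nested species-area relationship (SAR) records, for circles of growing area
around a focal point, how many species have already been encountered.  Each
species enters the curve at the area of the circle through its nearest
individual, so a realised SAR is just the sorted per-species minimum
distances converted to areas.  The expected curve is the equally weighted
mixture of the per-species minima cdfs on the area scale,

    S_M(A) = (1 / S_T) * sum_i L_i(A),

interpreted as the expected proportion of the community's ``S_T`` species
found within area ``A``; ``S_T * S_M(A)`` is the expected count.

On log-log axes the curve is triphasic, and the slopes of its three phases
are fitted here by ordinary least squares of log10(count) on log10(area)
over count-delimited windows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import (
    GEVMinParams,
    MinimaLaw,
    area_from_radius,
    gev_min_cdf,
    gev_min_pdf,
    radius_from_area,
)

__all__ = [
    "SARCurve",
    "PhaseFit",
    "sar_from_minima",
    "mixture_sar",
    "mixture_density",
    "loglog_slope",
    "phase_slopes",
    "mu_powerlaw_fit",
    "DEFAULT_SKIP_FIRST",
]

# Phase I fits exclude the first few species by default: at very small areas a
# realised curve deviates from the expectation because so few individuals are
# involved, a discreteness artefact rather than a property of the community.
DEFAULT_SKIP_FIRST = 5


@dataclass(frozen=True)
class SARCurve:
    """Ordered first-detection areas with cumulative species counts."""

    areas: np.ndarray    # nondecreasing, one entry per detected species
    counts: np.ndarray   # 1..S_obs
    S_T: int             # species in the community (>= S_obs)

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float)
        c = np.asarray(self.counts)
        if len(a) == 0:
            raise ValueError("empty SAR curve")
        if len(a) != len(c):
            raise ValueError("areas and counts must have equal length")
        if np.any(np.diff(a) < 0):
            raise ValueError("areas must be nondecreasing")
        if not np.array_equal(c, np.arange(1, len(c) + 1)):
            raise ValueError("counts must be 1..S_obs")
        if len(c) > self.S_T:
            raise ValueError("observed species exceed S_T")
        object.__setattr__(self, "areas", a)
        object.__setattr__(self, "counts", np.asarray(c, dtype=int))

    @property
    def s_obs(self) -> int:
        return len(self.counts)

    def count_at(self, area) -> np.ndarray:
        """Number of species whose first-detection area is <= ``area``."""
        return np.searchsorted(self.areas, np.asarray(area, dtype=float), side="right")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"area": self.areas, "cumulative_species": self.counts})


@dataclass(frozen=True)
class PhaseFit:
    """OLS fit of log10(count) on log10(area) over one window of a curve."""

    slope: float
    intercept: float
    stderr: float
    window: tuple[float, float]   # count window actually used
    n_points: int

    @property
    def ok(self) -> bool:
        return np.isfinite(self.slope)


_EMPTY_FIT = PhaseFit(slope=np.nan, intercept=np.nan, stderr=np.nan,
                      window=(np.nan, np.nan), n_points=0)


def sar_from_minima(minima, S_T: int | None = None, species_ids=None) -> SARCurve:
    """Assemble a SAR from per-species minimum distances.

    Distances are sorted ascending (stable, ties broken by species order or
    by ``species_ids``) and converted to areas ``A = pi r**2``.
    """
    m = np.asarray(minima, dtype=float)
    if m.size == 0:
        raise ValueError("no minima supplied")
    if np.any(m < 0):
        raise ValueError("minima must be non-negative")
    if species_ids is not None:
        order = np.lexsort((np.asarray(species_ids), m))
    else:
        order = np.argsort(m, kind="stable")
    areas = area_from_radius(m[order])
    return SARCurve(areas=areas, counts=np.arange(1, len(m) + 1),
                    S_T=int(S_T) if S_T is not None else len(m))


def _law_cdf_area(law, area: np.ndarray) -> np.ndarray:
    if isinstance(law, MinimaLaw):
        return law.cdf_area(area)
    if isinstance(law, GEVMinParams):
        # GEV fitted on the distance scale; change of variable r = sqrt(A/pi)
        return gev_min_cdf(radius_from_area(area), law)
    raise TypeError(f"unsupported law type {type(law).__name__}")


def mixture_sar(laws: Sequence, area) -> np.ndarray:
    """Expected proportion of species detected within each area of a grid.

    ``laws`` are per-species minima laws (``MinimaLaw`` or fitted
    ``GEVMinParams`` on the distance scale), mixed with equal weights
    ``1/S_T``.  Multiply by ``S_T`` for expected species counts.
    """
    if len(laws) == 0:
        raise ValueError("no minima laws supplied")
    area = np.atleast_1d(np.asarray(area, dtype=float))
    acc = np.zeros_like(area)
    for law in laws:
        acc += _law_cdf_area(law, area)
    return acc / len(laws)


def mixture_density(laws: Sequence, area) -> np.ndarray:
    """Density of first detections on the area scale (derivative of the mixture).

    Analytic for ``MinimaLaw`` objects carrying a parent pdf and for GEV
    parameters; falls back to central finite differences of the mixture cdf
    otherwise.
    """
    if len(laws) == 0:
        raise ValueError("no minima laws supplied")
    area = np.atleast_1d(np.asarray(area, dtype=float))

    def one(law):
        if isinstance(law, MinimaLaw) and law.parent_pdf is not None:
            return law.pdf_area(area)
        if isinstance(law, GEVMinParams):
            r = radius_from_area(area)
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(r > 0, gev_min_pdf(r, law) / (2.0 * np.pi * r), 0.0)
        # finite differences on the cdf
        return np.gradient(_law_cdf_area(law, area), area, edge_order=1)

    acc = np.zeros_like(area)
    for law in laws:
        acc += one(law)
    return acc / len(laws)


def _ols_loglog(areas: np.ndarray, counts: np.ndarray) -> tuple[float, float, float]:
    res = stats.linregress(np.log10(areas), np.log10(counts))
    return float(res.slope), float(res.intercept), float(res.stderr)


def loglog_slope(
    curve: SARCurve,
    count_window: tuple[float, float] | None = None,
    area_window: tuple[float, float] | None = None,
    min_points: int = 10,
) -> PhaseFit:
    """OLS slope of log10(count) on log10(area) over a window of the curve.

    The window is given either in cumulative species counts or in areas; the
    regression runs on the curve's own accumulation steps (no resampling).
    """
    if (count_window is None) == (area_window is None):
        raise ValueError("supply exactly one of count_window or area_window")
    c = curve.counts
    a = curve.areas
    if count_window is not None:
        lo, hi = count_window
        mask = (c >= lo) & (c <= hi)
    else:
        lo, hi = area_window
        mask = (a >= lo) & (a <= hi)
    mask &= a > 0
    if mask.sum() < min_points:
        raise ValueError(f"window contains {int(mask.sum())} points, need >= {min_points}")
    slope, intercept, stderr = _ols_loglog(a[mask], c[mask])
    cw = (float(c[mask].min()), float(c[mask].max()))
    return PhaseFit(slope=slope, intercept=intercept, stderr=stderr, window=cw,
                    n_points=int(mask.sum()))


def phase_slopes(
    curve: SARCurve,
    S_P_I_II: int,
    S_P_II_III: int,
    skip_first: int = DEFAULT_SKIP_FIRST,
    min_points: int = 10,
) -> tuple[PhaseFit, PhaseFit, PhaseFit]:
    """Slopes of the three SAR phases, delimited by the transition counts.

    Windows (in cumulative species counts): Phase I ``[1 + skip_first,
    S_P_I_II]``, Phase II ``[S_P_I_II, S_P_II_III]``, Phase III
    ``[S_P_II_III, S_obs]``.  A window with too few points yields a flagged
    (NaN) fit instead of raising, so the other phases are still returned.
    """
    if not 0 < S_P_I_II < S_P_II_III <= curve.S_T:
        raise ValueError("need 0 < S_P_I_II < S_P_II_III <= S_T")
    windows = [
        (1 + skip_first, S_P_I_II),
        (S_P_I_II, S_P_II_III),
        (S_P_II_III, curve.s_obs),
    ]
    fits = []
    for w in windows:
        try:
            fits.append(loglog_slope(curve, count_window=w, min_points=min_points))
        except ValueError:
            fits.append(_EMPTY_FIT)
    return tuple(fits)


@dataclass(frozen=True)
class PowerLawFit:
    beta: float
    implied_z: float
    stderr: float
    n_species: int


def mu_powerlaw_fit(
    ratio,
    mu,
    band: tuple[float, float] = (2.0, 4.0),
    min_species: int = 20,
) -> PowerLawFit:
    """Power-law exponent of the fitted GEV location against the range ratio.

    Within the intermediate band ``2 < upsilon_p/sigma_p < 4`` the location of
    the minima law grows almost as a power law, ``mu ~ (upsilon_p/sigma_p)**beta``;
    the reciprocal ``1/beta`` is the implied Phase II SAR exponent ``z``.
    """
    ratio = np.asarray(ratio, dtype=float)
    mu = np.asarray(mu, dtype=float)
    mask = (ratio > band[0]) & (ratio < band[1]) & np.isfinite(mu) & (mu > 0)
    if mask.sum() < min_species:
        raise ValueError(
            f"only {int(mask.sum())} species in ratio band {band}, need >= {min_species}")
    res = stats.linregress(np.log(ratio[mask]), np.log(mu[mask]))
    return PowerLawFit(beta=float(res.slope), implied_z=float(1.0 / res.slope),
                       stderr=float(res.stderr), n_species=int(mask.sum()))
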