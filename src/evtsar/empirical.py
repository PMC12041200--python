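"""Species-area curves from occurrence tables.

Implements the sampling scheme used on aggregated occurrence records (e.g.
GBIF exports): place a focal point inside the study region, take the largest
circle that stays inside the region boundary, record for every species the
nearest individual to the focal point, and build the nested SAR from those
minimum distances.  Focal points are resampled until a target number of
curves with at least ``min_species`` species is reached.  Per-species range
statistics (centre of gravity and the standard deviation of individual
distances to it) feed the transition-count predictions: a species counts
towards the Phase I-II (II-III) transition when the focal point lies within
2 (4) of its sigma_p of the range centre.

All geometry is planar Euclidean; coordinates must be pre-projected into an
equidistant projection so distances are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .sar_curves import SARCurve, sar_from_minima

__all__ = [
    "EmpiricalSARSet",
    "species_range_stats",
    "build_sar",
    "sample_sars",
    "mean_sar",
    "median_sar",
    "empirical_transitions",
    "aggregation_diagnostic",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_SPECIES = 50
DEFAULT_TARGET_COUNT = 200


@dataclass(frozen=True)
class EmpiricalSARSet:
    """SARs sampled from one occurrence table, with their focal geometry."""

    sars: tuple[SARCurve, ...]
    focal_points: np.ndarray    # (n, 2)
    max_radii: np.ndarray       # (n,)
    min_species: int
    attempts: int

    def __len__(self) -> int:
        return len(self.sars)

    @property
    def acceptance_rate(self) -> float:
        return len(self.sars) / self.attempts if self.attempts else np.nan

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for i, s in enumerate(self.sars):
            f = s.to_frame()
            f.insert(0, "sar_id", i)
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _require_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = {"species", "x", "y"} - set(table.columns)
    if missing:
        raise ValueError(f"occurrence table lacks columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("occurrence table is empty")
    return table


def species_range_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Centre of gravity and range scale per species.

    The centre is the coordinate-wise mean of a species' records; ``sigma_p``
    is the standard deviation (population, 1/n denominator) of the
    individuals' Euclidean distances to that centre.  Species with a single
    record get ``sigma_p = 0`` and ``single_record = True``.
    """
    table = _require_table(table)
    g = table.groupby("species", sort=True)
    cx = g["x"].mean()
    cy = g["y"].mean()
    n = g.size()
    dx = table["x"] - table["species"].map(cx)
    dy = table["y"] - table["species"].map(cy)
    d = np.hypot(dx, dy)
    # population sd of the distances to the centre
    d2m = d.pow(2).groupby(table["species"]).mean()
    dm = d.groupby(table["species"]).mean()
    sigma_p = np.sqrt(np.maximum(d2m - dm**2, 0.0))
    out = pd.DataFrame({
        "centre_x": cx, "centre_y": cy, "sigma_p": sigma_p,
        "n_records": n, "single_record": n == 1,
    })
    out.loc[out["single_record"], "sigma_p"] = 0.0
    return out


def build_sar(table: pd.DataFrame, focal: tuple[float, float], max_radius: float) -> SARCurve:
    """Nested SAR around ``focal``: per-species nearest record within ``max_radius``."""
    if max_radius <= 0:
        raise ValueError("max_radius must be > 0")
    table = _require_table(table)
    d = np.hypot(table["x"] - focal[0], table["y"] - focal[1])
    inside = d <= max_radius
    if not inside.any():
        raise ValueError("no records within max_radius of the focal point")
    mins = d[inside].groupby(table.loc[inside, "species"]).min().sort_index()
    return sar_from_minima(mins.to_numpy(), S_T=len(mins),
                           species_ids=np.arange(len(mins)))


def sample_sars(
    table: pd.DataFrame,
    boundary: Polygon,
    target_count: int = DEFAULT_TARGET_COUNT,
    min_species: int = DEFAULT_MIN_SPECIES,
    seed: int = 0,
    max_attempts: int | None = None,
) -> EmpiricalSARSet:
    """Sample SARs at random focal points inside a boundary polygon.

    Focal points are uniform over the polygon interior; each one's maximum
    radius is its distance to the polygon boundary (the sampled circle never
    leaves the region).  Focal points yielding fewer than ``min_species``
    species are rejected and redrawn until ``target_count`` curves are
    collected or ``max_attempts`` (default ``50 * target_count``) is reached.
    """
    table = _require_table(table)
    if target_count < 1:
        raise ValueError("target_count must be >= 1")
    if max_attempts is None:
        max_attempts = 50 * target_count
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = boundary.bounds
    xs = table["x"].to_numpy()
    ys = table["y"].to_numpy()
    sp = table["species"].to_numpy()

    sars, focals, radii = [], [], []
    attempts = 0
    while len(sars) < target_count and attempts < max_attempts:
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not boundary.contains(Point(x, y)):
            continue  # not an attempt: point was outside the region
        attempts += 1
        r = boundary.exterior.distance(Point(x, y))
        if r <= 0:
            continue
        d = np.hypot(xs - x, ys - y)
        inside = d <= r
        n_species = len(np.unique(sp[inside]))
        if n_species < min_species:
            continue
        mins = pd.Series(d[inside]).groupby(pd.Series(sp[inside])).min().sort_index()
        sars.append(sar_from_minima(mins.to_numpy(), S_T=len(mins)))
        focals.append((x, y))
        radii.append(r)
    if len(sars) < target_count:
        rate = len(sars) / attempts if attempts else 0.0
        raise RuntimeError(
            f"collected only {len(sars)}/{target_count} SARs after {attempts} "
            f"attempts (acceptance rate {rate:.3f}); relax min_species or enlarge the data")
    logger.info("sampled %d SARs in %d attempts (acceptance rate %.3f)",
                len(sars), attempts, len(sars) / attempts)
    return EmpiricalSARSet(sars=tuple(sars), focal_points=np.asarray(focals),
                           max_radii=np.asarray(radii), min_species=min_species,
                           attempts=attempts)


# --------------------------------------------------------------------------
# mean / median SAR by rank
# --------------------------------------------------------------------------

def _mean_ranks(sars: Sequence[SARCurve]) -> np.ndarray:
    """Per-SAR mean rank over species indices.

    At each species index k, SARs that reach k species are ranked by the area
    at which their k-th species appears (average ranks on ties); each SAR's
    mean rank averages the ranks over the indices it reaches.
    """
    n = len(sars)
    kmax = max(s.s_obs for s in sars)
    sums = np.zeros(n)
    cnts = np.zeros(n, dtype=int)
    for k in range(kmax):
        idx = [i for i, s in enumerate(sars) if s.s_obs > k]
        if len(idx) < 2:
            break  # a lone SAR at this depth carries no ranking information
        areas = np.array([sars[i].areas[k] for i in idx])
        ranks = stats.rankdata(areas, method="average")
        for j, i in enumerate(idx):
            sums[i] += ranks[j]
            cnts[i] += 1
    if np.any(cnts == 0):
        raise ValueError("some SARs share no species index with the others")
    return sums / cnts


def mean_sar(sars: Sequence[SARCurve]) -> SARCurve:
    """The member SAR whose mean rank is closest to the grand mean of mean ranks."""
    if len(sars) < 2:
        raise ValueError("need at least 2 SARs")
    mr = _mean_ranks(sars)
    return sars[int(np.argmin(np.abs(mr - mr.mean())))]  # first wins ties


def median_sar(sars: Sequence[SARCurve]) -> SARCurve:
    """The member SAR whose mean rank is closest to the median of mean ranks."""
    if len(sars) < 2:
        raise ValueError("need at least 2 SARs")
    mr = _mean_ranks(sars)
    return sars[int(np.argmin(np.abs(mr - np.median(mr))))]


# --------------------------------------------------------------------------
# empirical transition counts
# --------------------------------------------------------------------------

def empirical_transitions(
    table: pd.DataFrame,
    focal: tuple[float, float],
    k_values: Sequence[float] = (2.0, 4.0),
    max_radius: float | None = None,
) -> pd.DataFrame:
    """Species counts qualifying for each transition at a focal point.

    A species qualifies at multiplier ``k`` when the focal point lies within
    ``k * sigma_p`` of its range centre.  With ``max_radius`` set, only
    species with at least one record within that radius are considered
    (otherwise the whole species pool of the table is used).  Single-record
    species have ``sigma_p = 0``, never qualify, and are reported in the
    ``n_single_record`` column.
    """
    table = _require_table(table)
    if max_radius is not None:
        d = np.hypot(table["x"] - focal[0], table["y"] - focal[1])
        keep = table.loc[d <= max_radius, "species"].unique()
        pool = table[table["species"].isin(keep)]
    else:
        pool = table
    st = species_range_stats(pool)
    dist = np.hypot(st["centre_x"] - focal[0], st["centre_y"] - focal[1])
    rows = []
    for k in k_values:
        qualifies = (dist < k * st["sigma_p"]) & ~st["single_record"]
        rows.append({"k": k, "count": int(qualifies.sum()),
                     "n_species": len(st),
                     "n_single_record": int(st["single_record"].sum())})
    return pd.DataFrame(rows)


def aggregation_diagnostic(table: pd.DataFrame) -> pd.DataFrame:
    """Locations shared by records of more than one species.

    Aggregated (snapped) locations produce sudden spikes in species counts;
    they are reported, not corrected.
    """
    table = _require_table(table)
    g = table.groupby(["x", "y"])["species"].nunique()
    hot = g[g > 1].sort_values(ascending=False)
    return hot.rename("n_species").reset_index()
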