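"""Axial spherical representation, stereoplots and permutation statistics.

Axes (antipodally symmetric unit vectors) are canonicalized to the upper
hemisphere, expressed as longitude/latitude (longitude 0/90/180/270 =
posterior/lateral/anterior/medial, latitude 90 = distal long-axis pole) and
projected with the equal-angle (Wulff) stereographic projection.

Group comparisons follow the permutation scheme: exhaustive enumeration of
all size-preserving allocations when feasible, seeded Monte-Carlo
otherwise; the observed allocation is always counted, so p >= 1/N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from ._geometry import unit


class StatsError(ValueError):
    """Raised on degenerate statistical inputs."""


# ---------------------------------------------------------------------------
# Axes on the sphere


def canonicalize_axis(vector: np.ndarray) -> np.ndarray:
    """Map an axis to its canonical upper-hemisphere representative.

    Positive z (distal) component; equator ties broken toward anterior
    (negative x); the remaining ties toward positive y (lateral).
    """
    v = unit(np.asarray(vector, dtype=float))
    if v[2] < 0:
        v = -v
    elif v[2] == 0:
        if v[0] > 0:
            v = -v
        elif v[0] == 0 and v[1] < 0:
            v = -v
    return v


@dataclass(frozen=True)
class AxisOnSphere:
    """A unit 3D axis with antipodal equivalence, in (x, y, z) components."""

    vector: tuple[float, float, float]
    unstable: bool = False

    @classmethod
    def from_vector(cls, v: np.ndarray, unstable: bool = False) -> "AxisOnSphere":
        c = canonicalize_axis(v)
        return cls(tuple(float(x) for x in c), unstable=unstable)

    @classmethod
    def from_lonlat(cls, lon_deg: float, lat_deg: float) -> "AxisOnSphere":
        lon = math.radians(lon_deg)
        lat = math.radians(lat_deg)
        v = np.array(
            [math.cos(lat) * math.cos(lon), math.cos(lat) * math.sin(lon), math.sin(lat)]
        )
        return cls.from_vector(v)

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.vector)

    @property
    def lonlat(self) -> tuple[float, float]:
        return to_lonlat(self.xyz)

    @property
    def stereo_xy(self) -> tuple[float, float]:
        return stereo_project(*self.lonlat)


def to_lonlat(vector: np.ndarray) -> tuple[float, float]:
    """(longitude, latitude) in degrees of a (possibly non-canonical) vector.

    Longitude 0 = posterior (+x), 90 = lateral (+y), 180 = anterior (-x),
    270 = medial (-y); latitude 90 = distal pole (+z).
    """
    v = unit(np.asarray(vector, dtype=float))
    lat = math.degrees(math.asin(max(-1.0, min(1.0, v[2]))))
    lon = math.degrees(math.atan2(v[1], v[0])) % 360.0
    return lon, lat


def stereo_project(lon_deg: float, lat_deg: float) -> tuple[float, float]:
    """Equal-angle (Wulff) projection: radius = tan(colatitude / 2).

    The pole (latitude 90) maps to the origin; the equator to the unit
    circle.  Plot x points along longitude 0 (posterior), y along 90.
    """
    r = math.tan(math.radians(90.0 - lat_deg) / 2.0)
    lon = math.radians(lon_deg)
    return r * math.cos(lon), r * math.sin(lon)


def stereo_invert(x: float, y: float) -> tuple[float, float]:
    """Inverse of :func:`stereo_project` on the closed upper hemisphere."""
    r = math.hypot(x, y)
    lat = 90.0 - 2.0 * math.degrees(math.atan(r))
    lon = math.degrees(math.atan2(y, x)) % 360.0 if r > 0 else 0.0
    return lon, lat


# ---------------------------------------------------------------------------
# Distances and centroids


def haversine_deg(a: AxisOnSphere, b: AxisOnSphere, axial: bool = False) -> float:
    """Central angle in degrees between two axes via the haversine formula.

    With ``axial=True`` the antipodal identification is applied:
    min(d, 180 - d).
    """
    lon1, lat1 = a.lonlat
    lon2, lat2 = b.lonlat
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp = p2 - p1
    dl = math.radians(lon2 - lon1)
    h = math.sin(dp / 2.0) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2.0) ** 2
    d = math.degrees(2.0 * math.asin(min(1.0, math.sqrt(h))))
    if axial:
        d = min(d, 180.0 - d)
    return d


def spherical_centroid(axes: Sequence[AxisOnSphere], degenerate_tol: float = 1e-8) -> AxisOnSphere:
    """Renormalized vector mean of hemisphere-canonicalized axes.

    Raises when the resultant vanishes ("dispersed beyond centroid
    definition"); flags near-degenerate resultants as unstable.
    """
    if len(axes) == 0:
        raise StatsError("need at least one axis")
    vecs = np.array([ax.xyz for ax in axes])
    mean = vecs.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm < degenerate_tol:
        raise StatsError("dispersed beyond centroid definition (zero resultant)")
    return AxisOnSphere.from_vector(mean / norm, unstable=norm < 0.1)


# ---------------------------------------------------------------------------
# Permutation machinery


@dataclass
class PermutationResult:
    observed: float
    n_allocations: int
    mode: str  # 'exhaustive' or 'monte_carlo'
    p_value: float
    n_extreme: int
    seed: int | None = None
    n_excluded_allocations: int = 0
    excluded_points: list = field(default_factory=list)


def permutation_test_median(
    group_a: Sequence[float],
    group_b: Sequence[float],
    max_exact: int = 10**6,
    n_draws: int = 10**4,
    seed: int = 0,
) -> PermutationResult:
    """Exact/Monte-Carlo permutation test on |median(A) - median(B)|."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("empty group")
    pool = np.concatenate([a, b])
    n, n_a = pool.size, a.size
    observed = abs(float(np.median(a)) - float(np.median(b)))

    total = math.comb(n, n_a)
    if total <= max_exact:
        idx = np.fromiter(
            (i for comb in combinations(range(n), n_a) for i in comb), dtype=np.intp
        ).reshape(-1, n_a)
        mode = "exhaustive"
        n_alloc = total
    else:
        rng = np.random.default_rng(seed)
        idx = np.array([rng.permutation(n)[:n_a] for _ in range(n_draws)])
        mode = "monte_carlo"
        n_alloc = n_draws
    stats = np.empty(len(idx))
    chunk = 65536
    for lo in range(0, len(idx), chunk):
        sub = idx[lo : lo + chunk]
        med_a = np.median(pool[sub], axis=1)
        mask = np.ones((len(sub), n), dtype=bool)
        np.put_along_axis(mask, sub, False, axis=1)
        med_b = np.median(
            np.broadcast_to(pool, (len(sub), n))[mask].reshape(len(sub), n - n_a), axis=1
        )
        stats[lo : lo + len(sub)] = np.abs(med_a - med_b)
    if mode == "exhaustive":
        n_extreme = int(np.count_nonzero(stats >= observed - 1e-12))
        p = n_extreme / n_alloc
    else:
        n_extreme = int(np.count_nonzero(stats >= observed - 1e-12)) + 1
        p = n_extreme / (n_alloc + 1)
    return PermutationResult(observed, n_alloc, mode, p, n_extreme, seed=seed)


def permutation_test_sphere(
    group_a: Sequence[AxisOnSphere],
    group_b: Sequence[AxisOnSphere],
    axial: bool = True,
    max_exact: int = 10**6,
    n_draws: int = 10**4,
    seed: int = 0,
    exclude_a: Sequence[int] = (),
    exclude_b: Sequence[int] = (),
) -> PermutationResult:
    """Permutation test on the haversine distance between group centroids.

    ``exclude_a``/``exclude_b`` drop listed points before testing (the
    logged outlier-exclusion sensitivity option).  Allocations whose
    centroid is degenerate are excluded and counted.
    """
    a = [ax for i, ax in enumerate(group_a) if i not in set(exclude_a)]
    b = [ax for i, ax in enumerate(group_b) if i not in set(exclude_b)]
    if len(a) < 2 or len(b) < 2:
        raise StatsError("need at least two axes per group")
    vecs = np.array([ax.xyz for ax in a] + [ax.xyz for ax in b])
    n, n_a = len(vecs), len(a)

    def centroid_dist(ia: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized over allocations: returns (distance_deg, degenerate)."""
        suma = vecs[ia].sum(axis=1)
        sumb = vecs.sum(axis=0)[None, :] - suma
        na_ = np.linalg.norm(suma, axis=1)
        nb_ = np.linalg.norm(sumb, axis=1)
        degen = (na_ < 1e-8) | (nb_ < 1e-8)
        safe_a = np.where(degen[:, None], 1.0, na_[:, None])
        safe_b = np.where(degen[:, None], 1.0, nb_[:, None])
        dots = np.sum((suma / safe_a) * (sumb / safe_b), axis=1)
        if axial:
            dots = np.abs(dots)
        ang = np.degrees(np.arccos(np.clip(dots, -1.0, 1.0)))
        return ang, degen

    obs, obs_degen = centroid_dist(np.arange(n_a)[None, :])
    if obs_degen[0]:
        raise StatsError("observed group centroid is degenerate")
    observed = float(obs[0])

    total = math.comb(n, n_a)
    if total <= max_exact:
        idx = np.fromiter(
            (i for comb in combinations(range(n), n_a) for i in comb), dtype=np.intp
        ).reshape(-1, n_a)
        mode = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        idx = np.array([rng.permutation(n)[:n_a] for _ in range(n_draws)])
        mode = "monte_carlo"
    stats_parts = []
    degen_parts = []
    chunk = 65536
    for lo in range(0, len(idx), chunk):
        s_, d_ = centroid_dist(idx[lo : lo + chunk])
        stats_parts.append(s_)
        degen_parts.append(d_)
    stats = np.concatenate(stats_parts)
    degen = np.concatenate(degen_parts)
    n_excl = int(np.count_nonzero(degen))
    stats = stats[~degen]
    n_alloc = len(stats)
    if mode == "exhaustive":
        n_extreme = int(np.count_nonzero(stats >= observed - 1e-9))
        p = n_extreme / n_alloc
    else:
        n_extreme = int(np.count_nonzero(stats >= observed - 1e-9)) + 1
        p = n_extreme / (n_alloc + 1)
    return PermutationResult(
        observed,
        n_alloc,
        mode,
        p,
        n_extreme,
        seed=seed,
        n_excluded_allocations=n_excl,
        excluded_points=list(exclude_a) + [("b", i) for i in exclude_b],
    )


# ---------------------------------------------------------------------------
# Exact rank-sum


def exact_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value with midrank ties.

    The exact null distribution of the group-A rank sum is computed by
    dynamic programming over subsets (shift algorithm), so ties are handled
    exactly; p = P(|W - E[W]| >= |w_obs - E[W]|).
    """
    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise StatsError("empty group")
    pool = np.concatenate([a, b])
    n, n_a = pool.size, a.size
    ranks2 = np.rint(2.0 * rankdata(pool)).astype(np.int64)  # doubled midranks
    w_obs = int(ranks2[:n_a].sum())
    e_w = n_a * (n + 1)  # doubled-rank expectation, exact integer
    d_obs = abs(w_obs - e_w)

    max_sum = int(ranks2.sum())
    # dp[k][s] = number of k-subsets of processed ranks with doubled sum s
    dp = np.zeros((n_a + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        for k in range(n_a, 0, -1):  # descending so dp[k-1] is still pristine
            dp[k, r:] += dp[k - 1, : max_sum + 1 - r]
    counts = dp[n_a]
    sums = np.arange(max_sum + 1)
    extreme = np.abs(sums - e_w) >= d_obs
    p = float(counts[extreme].sum() / counts.sum())
    return min(1.0, p)
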