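"""Point-pattern statistics for spot maps.

Two questions about the spatial arrangement of confirmed spots:

1. Are spot x-coordinates uniform along the proximodistal axis? Tested with
   the Anderson-Darling statistic against a fully specified uniform law on
   fixed bounds (case 0: no parameters estimated), p-value by parametric
   Monte Carlo or by the asymptotic null distribution.

2. Are spots aggregated? Tested with the Clark-Evans index
   ``R = r_obs / r_exp``, the ratio of the mean nearest-neighbour distance
   to its expectation under complete spatial randomness (CSR). ``R < 1``
   indicates aggregation. The Donnelly edge correction adjusts both the
   expectation and the variance for the bounded rectangular study region:

   ``r_exp = 0.5*sqrt(A/n) + (0.0514 + 0.0412/sqrt(n)) * P/n``
   ``Var(r_mean) = 0.0703*A/n^2 + 0.037*P*sqrt(A)/n^2.5``

   with A the region area and P its perimeter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

from .spot_model import SpotTable, StudyRegion, assign_segment

__all__ = [
    "PointPattern",
    "ADResult",
    "ClarkEvansResult",
    "InsufficientSampleError",
    "ad_statistic",
    "ad_uniform",
    "nn_distances",
    "clark_evans",
    "segment_counts",
    "segment_totals",
]


class InsufficientSampleError(ValueError):
    """Too few points for the requested statistic."""


@dataclass(frozen=True)
class PointPattern:
    """A planar point pattern within a bounded study region."""

    points: np.ndarray  # (n, 2) float array
    region: StudyRegion

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and (
            pts[:, 0].min() < 0
            or pts[:, 0].max() > self.region.length_px
            or pts[:, 1].min() < 0
            or pts[:, 1].max() > self.region.width_px
        ):
            raise ValueError("points outside study region")

    @property
    def n(self) -> int:
        return len(self.points)

    @classmethod
    def from_table(
        cls, table: SpotTable, participant_id: str | None = None
    ) -> "PointPattern":
        """Pattern of confirmed spots, pooled across sessions.

        Unconfirmed spots are excluded from all spatial analyses.
        """
        recs = table.confirmed().records
        if participant_id is not None:
            recs = [r for r in recs if r.participant_id == participant_id]
        pts = np.array([(r.x_px, r.y_px) for r in recs], dtype=float).reshape(-1, 2)
        return cls(pts, table.region)


@dataclass(frozen=True)
class ADResult:
    a2: float
    p_value: float
    n: int
    lower: float
    upper: float
    p_method: str


@dataclass(frozen=True)
class ClarkEvansResult:
    r_obs: float
    r_exp: float
    R: float
    z: float
    p_value: float
    correction: str
    n: int
    area_px2: float
    perimeter_px: float


def ad_statistic(xs, lower: float, upper: float) -> float:
    """Anderson-Darling A^2 against the uniform law on [lower, upper]."""
    u = _rescale(np.asarray(xs, dtype=float), lower, upper)
    return float(_a2_rows(np.sort(u)[None, :])[0])


def _rescale(xs: np.ndarray, lower: float, upper: float) -> np.ndarray:
    if upper <= lower:
        raise ValueError("upper bound must exceed lower bound")
    if xs.min() < lower or xs.max() > upper:
        raise ValueError("data outside [lower, upper]")
    u = (xs - lower) / (upper - lower)
    eps = np.finfo(float).eps
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn(
            "data on a closed bound clamped inward by machine epsilon",
            stacklevel=3,
        )
        u = np.clip(u, eps, 1.0 - eps)
    return u


def _a2_rows(u_sorted: np.ndarray) -> np.ndarray:
    """A^2 per row of an already-sorted (B, n) array of uniforms in (0,1)."""
    n = u_sorted.shape[1]
    i = np.arange(1, n + 1)
    weights = 2.0 * i - 1.0
    terms = weights * (np.log(u_sorted) + np.log1p(-u_sorted[:, ::-1]))
    return -n - terms.sum(axis=1) / n


def _adinf(z: float) -> float:
    """Limiting null CDF of A^2 (Marsaglia & Marsaglia approximation)."""
    if z <= 0:
        return 0.0
    if z < 2.0:
        return (
            z**-0.5
            * np.exp(-1.2337141 / z)
            * (
                2.00012
                + (
                    0.247105
                    - (0.0649821 - (0.0347962 - (0.011672 - 0.00168691 * z) * z) * z)
                    * z
                )
                * z
            )
        )
    return float(
        np.exp(
            -np.exp(
                1.0776
                - (2.30695 - (0.43424 - (0.082433 - (0.008056 - 0.0003146 * z) * z) * z) * z)
                * z
            )
        )
    )


def _ad_cdf(n: int, z: float) -> float:
    """Finite-n null CDF of A^2: limiting CDF plus small-sample correction."""
    x = _adinf(z)
    if x > 0.8:
        v = (
            -130.2137
            + (745.2337 - (1705.091 - (1950.646 - (1116.360 - 255.7844 * x) * x) * x) * x)
            * x
        ) / n
        return min(max(x + v, 0.0), 1.0)
    c = 0.01265 + 0.1757 / n
    if x < c:
        t = x / c
        t = np.sqrt(t) * (1.0 - t) * (49.0 * t - 102.0)
        return min(max(x + t * (0.0037 / n**2 + 0.00078 / n + 0.00006) / n, 0.0), 1.0)
    t = (x - c) / (0.8 - c)
    t = (
        -0.00022633
        + (6.54034 - (14.6538 - (14.458 - (8.259 - 1.91864 * t) * t) * t) * t) * t
    )
    return min(max(x + t * (0.04213 + 0.01365 / n) / n, 0.0), 1.0)


def ad_uniform(
    xs,
    lower: float = 0.0,
    upper: float = 1200.0,
    p_method: str = "monte_carlo",
    n_mc: int = 10_000,
    rng=None,
) -> ADResult:
    """Anderson-Darling test of uniformity on fixed bounds.

    Parameters
    ----------
    xs
        Sample of coordinates; at least 3 values, all within
        ``[lower, upper]`` (values on a closed bound are clamped inward by
        machine epsilon with a warning).
    p_method
        ``monte_carlo`` (default): parametric Monte Carlo with ``n_mc``
        uniform null replicates, ``p = (1 + #{A2* >= A2}) / (n_mc + 1)``.
        ``asymptotic``: finite-n corrected limiting distribution.
    rng
        ``numpy.random.Generator`` or seed for the Monte Carlo replicates.
    """
    xs = np.asarray(xs, dtype=float)
    n = xs.size
    if n < 3:
        raise InsufficientSampleError(
            f"need at least 3 points to test a distribution, got {n}"
        )
    a2 = ad_statistic(xs, lower, upper)
    if p_method == "monte_carlo":
        gen = np.random.default_rng(rng)
        null = _a2_rows(np.sort(gen.random((n_mc, n)), axis=1))
        p = (1.0 + np.count_nonzero(null >= a2)) / (n_mc + 1.0)
    elif p_method == "asymptotic":
        p = 1.0 - _ad_cdf(n, a2)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return ADResult(
        a2=a2, p_value=float(p), n=int(n), lower=lower, upper=upper,
        p_method=p_method,
    )


def nn_distances(pattern: PointPattern) -> np.ndarray:
    """Euclidean distance from each point to its nearest other point."""
    if pattern.n < 2:
        raise InsufficientSampleError(
            f"nearest-neighbour distances need >= 2 points, got {pattern.n}"
        )
    tree = cKDTree(pattern.points)
    dists, _ = tree.query(pattern.points, k=2)
    return dists[:, 1]


def clark_evans(pattern: PointPattern, correction: str = "donnelly") -> ClarkEvansResult:
    """Clark-Evans aggregation test against CSR on the bounded region.

    ``correction="none"`` uses the classical expectation
    ``r_exp = 0.5/sqrt(n/A)`` and variance ``(4-pi)A/(4*pi*n^2)``;
    ``correction="donnelly"`` applies the edge-corrected expectation and
    variance (module docstring). The z test is two-sided.
    """
    n = pattern.n
    if n < 2:
        raise InsufficientSampleError(f"Clark-Evans needs >= 2 points, got {n}")
    area = pattern.region.area_px2
    perim = pattern.region.perimeter_px
    if area <= 0:
        raise ValueError("region area must be positive")

    r_obs = float(nn_distances(pattern).mean())
    if correction == "none":
        r_exp = 0.5 * np.sqrt(area / n)
        var = (4.0 - np.pi) * area / (4.0 * np.pi * n**2)
    elif correction == "donnelly":
        r_exp = 0.5 * np.sqrt(area / n) + (0.0514 + 0.0412 / np.sqrt(n)) * perim / n
        var = 0.0703 * area / n**2 + 0.037 * perim * np.sqrt(area) / n**2.5
    else:
        raise ValueError(f"unknown correction {correction!r}")

    z = (r_obs - r_exp) / np.sqrt(var)
    p = 2.0 * norm.sf(abs(z))
    return ClarkEvansResult(
        r_obs=r_obs,
        r_exp=float(r_exp),
        R=r_obs / float(r_exp),
        z=float(z),
        p_value=float(p),
        correction=correction,
        n=n,
        area_px2=area,
        perimeter_px=perim,
    )


def segment_counts(table: SpotTable) -> dict[tuple[str, int], int]:
    """Spot counts per (participant, proximodistal segment).

    Every (participant, segment) cell present in the region is reported,
    including zeros, for each participant in the table.
    """
    counts: dict[tuple[str, int], int] = {
        (p, k): 0
        for p in table.participants()
        for k in range(1, table.region.n_segments + 1)
    }
    for rec in table.records:
        counts[(rec.participant_id, assign_segment(rec.x_px, table.region))] += 1
    return counts


def segment_totals(counts: dict[tuple[str, int], int]) -> dict[int, int]:
    """Marginal totals by segment from :func:`segment_counts` output."""
    totals: dict[int, int] = {}
    for (_, seg), c in counts.items():
        totals[seg] = totals.get(seg, 0) + c
    return dict(sorted(totals.items()))
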