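"""Spatial statistics of nuclear-pore-complex point patterns.

Tangential TEM views of the nuclear surface give 2-D pore-center coordinates
inside a rectangular observation window. This module computes the morphometric
quantities used to contrast wild-type and mutant envelopes: per-pore
nearest-neighbor (NN) distances, the fraction of pores in configured distance
bins, pore density per μm² and between-condition density ratios, a seeded
permutation test for a difference in mean NN distance, and a contour
circularity metric (4πA/P²) for nuclear outlines.

Distances are in nm; window areas are reported in μm². By default no edge
correction is applied (pores near the window border simply take their nearest
in-window neighbor). Two optional corrections are available for sensitivity
analysis: a periodic ("torus") metric, under which the homogeneous Poisson
nearest-neighbor law P(NN > r) = exp(-ρπr²) holds exactly, and a border
exclusion that drops points within a guard distance of the window edge as NN
"centers" while keeping them as candidate neighbors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

__all__ = [
    "PointPattern",
    "SpacingSummary",
    "PermutationResult",
    "nn_distances",
    "bin_fractions",
    "density_and_ratio",
    "compare_conditions",
    "circularity",
]

NM2_PER_UM2 = 1.0e6


@dataclass(frozen=True)
class PointPattern:
    """2-D point coordinates (nm) in a rectangular window anchored at (0,0)."""

    points: np.ndarray  # shape (n, 2), nm
    window: tuple[float, float]  # (width_nm, height_nm)
    condition: str = ""
    abnormal: np.ndarray | None = None  # optional per-point boolean flags

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        w, h = self.window
        if w <= 0 or h <= 0:
            raise ValueError("window side lengths must be positive")
        if pts.size and (
            pts[:, 0].min() < 0
            or pts[:, 1].min() < 0
            or pts[:, 0].max() > w
            or pts[:, 1].max() > h
        ):
            raise ValueError("points fall outside the observation window")
        if self.abnormal is not None and len(self.abnormal) != len(pts):
            raise ValueError("abnormal flags must align with points")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def area_um2(self) -> float:
        return self.window[0] * self.window[1] / NM2_PER_UM2

    @property
    def density_per_um2(self) -> float:
        return self.n / self.area_um2


@dataclass(frozen=True)
class SpacingSummary:
    """Per-point NN distances (nm), their mean, and the pattern density."""

    nn_distances_nm: np.ndarray
    mean_nn_nm: float
    density_per_um2: float
    edge_correction: str = "none"


@dataclass(frozen=True)
class PermutationResult:
    p_value: float
    observed_diff: float
    n_perm: int


def nn_distances(
    pattern: PointPattern,
    edge_correction: str = "none",
    border_exclusion_nm: float | None = None,
) -> SpacingSummary:
    """Nearest-neighbor distance of every point to any other point.

    Parameters
    ----------
    edge_correction : {"none", "torus"}
        "none" (default) measures plain in-window distances; "torus" wraps the
        window periodically, removing edge bias for stationary processes.
    border_exclusion_nm : float, optional
        If given (with ``edge_correction="none"``), points closer than this to
        the window edge are excluded as NN centers but retained as neighbors.
    """
    pts = pattern.points
    if len(pts) < 2:
        raise ValueError("nearest-neighbor distances need at least 2 points")
    if edge_correction == "torus":
        if border_exclusion_nm is not None:
            raise ValueError("border exclusion is incompatible with the torus metric")
        # cKDTree's periodic boxsize requires points strictly inside [0, L)
        w, h = pattern.window
        wrapped = np.remainder(pts, [w, h])
        tree = cKDTree(wrapped, boxsize=[w, h])
        d, _ = tree.query(wrapped, k=2)
        nn = d[:, 1]
    elif edge_correction == "none":
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        nn = d[:, 1]
        if border_exclusion_nm is not None:
            r = float(border_exclusion_nm)
            if r < 0:
                raise ValueError("border exclusion must be >= 0")
            w, h = pattern.window
            inner = (
                (pts[:, 0] >= r)
                & (pts[:, 0] <= w - r)
                & (pts[:, 1] >= r)
                & (pts[:, 1] <= h - r)
            )
            nn = nn[inner]
            if nn.size == 0:
                raise ValueError("border exclusion removed every point")
    else:
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    return SpacingSummary(
        nn_distances_nm=nn,
        mean_nn_nm=float(nn.mean()),
        density_per_um2=pattern.density_per_um2,
        edge_correction=edge_correction,
    )


def _normalize_bins(
    bins: Sequence[float] | Sequence[tuple[float, float]],
) -> list[tuple[float, float]]:
    seq = list(bins)
    if not seq:
        raise ValueError("bins must be non-empty")
    if np.isscalar(seq[0]):
        edges = [float(b) for b in seq]
        if edges[0] != 0:
            raise ValueError("bin breakpoints must start at 0")
        if any(e2 <= e1 for e1, e2 in zip(edges, edges[1:])):
            raise ValueError("bin breakpoints must be strictly increasing")
        intervals = [(e1, e2) for e1, e2 in zip(edges, edges[1:])]
        intervals.append((edges[-1], math.inf))
    else:
        intervals = [(float(lo), float(hi)) for lo, hi in seq]
    # validate a contiguous, non-overlapping partition of [0, inf)
    intervals.sort()
    if intervals[0][0] != 0:
        raise ValueError("bins must cover [0, inf) starting at 0")
    for (lo1, hi1), (lo2, hi2) in zip(intervals, intervals[1:]):
        if hi1 > lo2:
            raise ValueError(f"overlapping bins: ({lo1},{hi1}) and ({lo2},{hi2})")
        if hi1 < lo2:
            raise ValueError(f"gap between bins at {hi1}-{lo2}")
    if intervals[-1][1] != math.inf:
        raise ValueError("last bin must extend to infinity")
    return intervals


def bin_fractions(
    summary: SpacingSummary | np.ndarray,
    bins: Sequence[float] | Sequence[tuple[float, float]],
) -> dict[tuple[float, float], float]:
    """Fraction of NN distances in each bin of a partition of [0, ∞).

    ``bins`` is either a list of breakpoints starting at 0 (e.g. ``[0, 30,
    60, 90]``, last bin open-ended) or explicit ``(lo, hi)`` intervals. The
    first bin is closed on both sides, subsequent bins half-open ``(lo, hi]``,
    so the intervals partition the line and the fractions sum to 1.
    """
    nn = (
        summary.nn_distances_nm
        if isinstance(summary, SpacingSummary)
        else np.asarray(summary, dtype=float)
    )
    if nn.size == 0:
        raise ValueError("no distances to bin")
    intervals = _normalize_bins(bins)
    out: dict[tuple[float, float], float] = {}
    for i, (lo, hi) in enumerate(intervals):
        if i == 0:
            mask = (nn >= lo) & (nn <= hi)
        else:
            mask = (nn > lo) & (nn <= hi)
        out[(lo, hi)] = float(mask.mean())
    return out


def density_and_ratio(
    a: PointPattern, b: PointPattern
) -> tuple[float, float, float]:
    """Pore densities (per μm²) of two patterns and the ratio b/a."""
    if a.n == 0 or b.n == 0:
        raise ValueError("both patterns must be non-empty")
    da, db = a.density_per_um2, b.density_per_um2
    return da, db, db / da


def compare_conditions(
    a_distances: np.ndarray,
    b_distances: np.ndarray,
    n_perm: int = 9999,
    seed: int | None = None,
) -> PermutationResult:
    """Two-sided permutation test for a difference in mean NN distance.

    The observed statistic is mean(a) − mean(b); group labels are permuted
    ``n_perm`` times and the p-value is (1 + #{|Δ_perm| ≥ |Δ_obs|}) /
    (n_perm + 1), so p ∈ (0, 1] and identical samples give p = 1. The test is
    deterministic for a fixed seed.
    """
    a = np.asarray(a_distances, dtype=float).ravel()
    b = np.asarray(b_distances, dtype=float).ravel()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)
    obs = a.mean() - b.mean()
    # vectorized label permutations: each row is one shuffled pooling
    idx = np.argsort(rng.random((n_perm, len(pooled))), axis=1)
    perm = pooled[idx]
    diffs = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
    count = int(np.sum(np.abs(diffs) >= abs(obs) - 1e-12))
    p = (1 + count) / (n_perm + 1)
    return PermutationResult(p_value=float(p), observed_diff=float(obs), n_perm=n_perm)


def circularity(vertices_nm: np.ndarray | Sequence[Sequence[float]]) -> float:
    """Isoperimetric circularity 4πA/P² of a simple closed polygon.

    Equals 1 for a circle (in the many-vertex limit) and decreases as the
    contour becomes lobulated or dented at fixed area.
    """
    verts = np.asarray(vertices_nm, dtype=float).reshape(-1, 2)
    if len(verts) < 3:
        raise ValueError("a closed contour needs at least 3 vertices")
    poly = Polygon(verts)
    if not poly.is_valid or not poly.is_simple:
        raise ValueError("contour polygon is self-intersecting or degenerate")
    area = poly.area
    perim = poly.length
    if area <= 0 or perim <= 0:
        raise ValueError("degenerate polygon")
    return 4.0 * math.pi * area / perim**2
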