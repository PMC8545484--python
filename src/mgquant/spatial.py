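"""Spatial statistics of 2D soma point patterns.

Density (cells/mm²), nearest-neighbour distance (NND) statistics and the
regularity index (mean NND / SD of NND; ≈1.91 for a 2D Poisson pattern,
larger for regular mosaics).  Distances are plain Euclidean by default; a
toroidal metric is available for validating against closed-form Poisson
expectations without edge effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

#: Regularity index of an ideal 2D Poisson pattern, 1/sqrt(4/pi - 1).
POISSON_REGULARITY_INDEX = 1.0 / math.sqrt(4.0 / math.pi - 1.0)


@dataclass
class PointPattern:
    """Point coordinates (µm) inside a rectangular field of view."""

    points: np.ndarray  # (n, 2) columns x, y
    fov_width_um: float
    fov_height_um: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if not (self.fov_width_um > 0 and self.fov_height_um > 0):
            raise ValueError("FOV dimensions must be positive")
        if self.points.size and (
            (self.points[:, 0] < 0).any() or (self.points[:, 0] > self.fov_width_um).any()
            or (self.points[:, 1] < 0).any() or (self.points[:, 1] > self.fov_height_um).any()
        ):
            raise ValueError("all points must lie inside the FOV")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def area_um2(self) -> float:
        return self.fov_width_um * self.fov_height_um


@dataclass
class SpatialReport:
    density_per_mm2: float
    mean_nnd_um: float
    sd_nnd_um: float
    regularity_index: float
    n: int


def density(pattern: PointPattern) -> float:
    """Point density in cells/mm²."""
    return pattern.n / (pattern.area_um2 / 1e6)


def nearest_neighbor_distances(pattern: PointPattern, toroidal: bool = False) -> np.ndarray:
    """Distance from each point to its nearest other point.

    With ``toroidal=True`` the FOV is wrapped (periodic boundary) so that
    edge points see neighbours across the boundary — useful for comparing
    against closed-form Poisson results.
    """
    if pattern.n < 2:
        raise ValueError("NND requires at least 2 points")
    if toroidal:
        tree = cKDTree(
            pattern.points, boxsize=[pattern.fov_width_um, pattern.fov_height_um]
        )
    else:
        tree = cKDTree(pattern.points)
    dist, _ = tree.query(pattern.points, k=2)
    return dist[:, 1]


def nnd_stats(
    pattern: PointPattern, toroidal: bool = False, ddof: int = 0
) -> tuple[float, float]:
    """Mean and SD of the NND distribution (population SD by default)."""
    d = nearest_neighbor_distances(pattern, toroidal=toroidal)
    return float(d.mean()), float(d.std(ddof=ddof))


def regularity_index(
    pattern: PointPattern, toroidal: bool = False, ddof: int = 0
) -> float:
    """Mean NND divided by SD of NND; +inf (with a warning) if SD is zero."""
    mean, sd = nnd_stats(pattern, toroidal=toroidal, ddof=ddof)
    if sd == 0.0:
        warnings.warn("NND standard deviation is zero; regularity index is infinite")
        return math.inf
    return mean / sd


def analyze_pattern(
    pattern: PointPattern, toroidal: bool = False, ddof: int = 0
) -> SpatialReport:
    """Density, NND statistics and regularity index for one FOV."""
    if pattern.n < 2:
        return SpatialReport(density(pattern), math.nan, math.nan, math.nan, pattern.n)
    mean, sd = nnd_stats(pattern, toroidal=toroidal, ddof=ddof)
    ri = mean / sd if sd > 0 else math.inf
    return SpatialReport(density(pattern), mean, sd, ri, pattern.n)
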