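"""Synthetic 2D point patterns: Poisson, jittered lattice, clustered."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..spatial import PointPattern

MODES = ("poisson", "jittered_lattice", "clustered")


@dataclass(frozen=True)
class PatternGenSpec:
    mode: str = "poisson"
    intensity_per_um2: float = 1e-4  # 100 cells/mm²
    fov_um: float = 640.0
    jitter_sd_um: float = 0.0
    cluster_size: int = 5  # mean offspring per cluster (clustered mode)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not self.intensity_per_um2 > 0:
            raise ValueError("intensity must be positive")
        if self.jitter_sd_um < 0:
            raise ValueError("jitter_sd_um must be >= 0")


def gen_pattern(spec: PatternGenSpec) -> PointPattern:
    """Simulate a point pattern in a square FOV.

    ``poisson``: count ~ Poisson(intensity × area), positions uniform.
    ``jittered_lattice``: square lattice at spacing 1/√intensity with
    isotropic Gaussian jitter, wrapped toroidally so counts are preserved.
    ``clustered``: Thomas-like process — Poisson parents, Gaussian
    offspring with SD ``jitter_sd_um``, wrapped toroidally.
    """
    rng = np.random.default_rng(spec.seed)
    area = spec.fov_um ** 2

    if spec.mode == "poisson":
        n = rng.poisson(spec.intensity_per_um2 * area)
        pts = rng.uniform(0.0, spec.fov_um, size=(n, 2))
    elif spec.mode == "jittered_lattice":
        spacing = 1.0 / np.sqrt(spec.intensity_per_um2)
        coords = np.arange(spacing / 2.0, spec.fov_um, spacing)
        gx, gy = np.meshgrid(coords, coords)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        if spec.jitter_sd_um:
            pts = pts + rng.normal(0.0, spec.jitter_sd_um, size=pts.shape)
            pts = np.mod(pts, spec.fov_um)
    else:  # clustered
        mean_offspring = max(1, spec.cluster_size)
        n_parents = rng.poisson(spec.intensity_per_um2 * area / mean_offspring)
        sd = spec.jitter_sd_um if spec.jitter_sd_um > 0 else spec.fov_um / 50.0
        children = []
        for _ in range(n_parents):
            parent = rng.uniform(0.0, spec.fov_um, size=2)
            k = rng.poisson(mean_offspring)
            if k:
                children.append(parent + rng.normal(0.0, sd, size=(k, 2)))
        pts = np.vstack(children) if children else np.empty((0, 2))
        pts = np.mod(pts, spec.fov_um)

    # guard against points landing exactly on the closed upper boundary
    pts = np.clip(pts, 0.0, np.nextafter(spec.fov_um, 0.0))
    return PointPattern(pts, spec.fov_um, spec.fov_um)
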