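"""Bead-phagocytosis quantification.

Assigns 3-µm bead centroids to labelled cell masks across a confocal
z-stack (2-µm steps by default) and reports the phagocytic index: the
percentage of cells containing at least ``min_beads`` internalised beads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class UndefinedIndexError(ValueError):
    """Phagocytic index is undefined for a scene with zero cells."""


@dataclass
class CellBeadScene:
    """Labelled cell masks plus bead centroids in physical coordinates.

    ``masks`` has shape (z, y, x) with positive integer labels per cell
    (0 = background); bead positions are in µm with z measured from the
    first plane.
    """

    masks: np.ndarray
    bead_xyz_um: np.ndarray  # (n_beads, 3) columns x, y, z
    pixel_size_um: float
    z_step_um: float = 2.0

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError("masks must be a (z, y, x) stack")
        self.bead_xyz_um = np.asarray(self.bead_xyz_um, dtype=float).reshape(-1, 3)
        if not (self.pixel_size_um > 0 and self.z_step_um > 0):
            raise ValueError("pixel_size_um and z_step_um must be positive")

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels)

    @property
    def cell_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.masks) if v > 0]


@dataclass
class PhagocytosisReport:
    n_cells: int
    n_phagocytic: int
    phagocytic_pct: float
    bead_counts: dict[int, int]
    fov_has_phagocytic: bool
    min_beads: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.phagocytic_pct <= 100):
            raise ValueError("phagocytic_pct must be in [0, 100]")
        if self.n_phagocytic > self.n_cells:
            raise ValueError("n_phagocytic cannot exceed n_cells")


def assign_beads(scene: CellBeadScene) -> tuple[dict[int, int], int]:
    """Per-cell internal bead counts.

    A bead belongs to cell ``c`` iff its centroid pixel lies inside c's
    mask at the nearest z-plane; each bead is assigned to at most one cell.
    Beads outside the stack are ignored with a warning.  Returns
    (counts by cell label, number of unassigned beads).
    """
    nz, ny, nx = scene.masks.shape
    counts = {lab: 0 for lab in scene.cell_labels}
    unassigned = 0
    for x, y, z in scene.bead_xyz_um:
        zi = int(round(z / scene.z_step_um))
        xi = int(round(x / scene.pixel_size_um))
        yi = int(round(y / scene.pixel_size_um))
        if not (0 <= zi < nz and 0 <= yi < ny and 0 <= xi < nx):
            warnings.warn(f"bead at ({x:.1f}, {y:.1f}, {z:.1f}) µm outside stack; ignored")
            unassigned += 1
            continue
        lab = int(scene.masks[zi, yi, xi])
        if lab > 0:
            counts[lab] += 1
        else:
            unassigned += 1
    return counts, unassigned


def phagocytic_index(
    counts: dict[int, int],
    n_cells: int | None = None,
    min_beads: int = 1,
) -> PhagocytosisReport:
    """Percentage of cells with at least ``min_beads`` internalised beads."""
    n_cells = len(counts) if n_cells is None else n_cells
    if n_cells < 1:
        raise UndefinedIndexError("phagocytic index undefined with zero cells")
    n_phago = sum(1 for c in counts.values() if c >= min_beads)
    return PhagocytosisReport(
        n_cells=n_cells,
        n_phagocytic=n_phago,
        phagocytic_pct=100.0 * n_phago / n_cells,
        bead_counts=dict(counts),
        fov_has_phagocytic=n_phago >= 1,
        min_beads=min_beads,
    )


def fov_occurrence(reports: list[PhagocytosisReport]) -> float:
    """Percentage of FOVs containing at least one phagocytic cell."""
    if not reports:
        raise ValueError("need at least one FOV report")
    return 100.0 * sum(r.fov_has_phagocytic for r in reports) / len(reports)


def analyze_scene(scene: CellBeadScene, min_beads: int = 1) -> PhagocytosisReport:
    """Convenience wrapper: assign beads then compute the index."""
    counts, _ = assign_beads(scene)
    return phagocytic_index(counts, n_cells=scene.n_cells, min_beads=min_beads)
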