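"""Synthetic cell-mask/bead scenes for the phagocytosis assay.

Cells are rendered as labelled disks spanning a contiguous range of
z-planes; 3-µm beads are placed with their centroid on a pixel centre so
that containment ground truth is exact under nearest-pixel lookup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..phagocytosis import CellBeadScene

BEAD_DIAMETER_UM = 3.0


@dataclass(frozen=True)
class SceneGenSpec:
    n_cells: int = 12
    frac_phagocytic: float = 0.5
    beads_per_phagocytic_cell: int = 1
    n_external_beads: int = 5
    fov_um: float = 106.0
    z_planes: int = 5
    z_step_um: float = 2.0
    pixel_size_um: float = 0.5
    cell_radius_um: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_phagocytic <= 1.0:
            raise ValueError("frac_phagocytic must be in [0, 1]")
        if self.beads_per_phagocytic_cell < 1:
            raise ValueError("beads_per_phagocytic_cell must be >= 1")
        if self.n_cells < 0 or self.n_external_beads < 0:
            raise ValueError("counts must be non-negative")
        if self.z_planes < 1:
            raise ValueError("need at least one z-plane")


@dataclass
class SceneTruth:
    """Ground truth: internal bead counts per cell label and bead table."""

    internal_counts: dict[int, int]
    bead_cell_labels: list[int]  # 0 = external, aligned with scene.bead_xyz_um rows

    @property
    def n_phagocytic(self) -> int:
        return sum(1 for c in self.internal_counts.values() if c >= 1)


def gen_scene(spec: SceneGenSpec) -> tuple[CellBeadScene, SceneTruth]:
    """Simulate a labelled z-stack of cells with internal/external beads.

    Exactly ``round(n_cells × frac_phagocytic)`` cells receive
    ``beads_per_phagocytic_cell`` beads whose centroids lie inside the
    cell's mask at one of its z-planes; external beads are placed on
    background pixels.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = int(round(spec.fov_um / spec.pixel_size_um))
    masks = np.zeros((spec.z_planes, n_px, n_px), dtype=np.int32)

    r_px = spec.cell_radius_um / spec.pixel_size_um
    yy, xx = np.mgrid[0:n_px, 0:n_px]

    # non-overlapping cell placement; each cell spans a contiguous z-range
    centers: list[np.ndarray] = []
    cell_z: dict[int, tuple[int, int]] = {}
    for label in range(1, spec.n_cells + 1):
        for _ in range(1000):
            c = rng.uniform(r_px, n_px - r_px, size=2)  # (y, x) in pixels
            if all(np.hypot(*(c - prev)) >= 2.2 * r_px for prev in centers):
                break
        else:
            raise ValueError("could not place non-overlapping cells; reduce n_cells")
        centers.append(c)
        z0 = int(rng.integers(0, spec.z_planes))
        z1 = min(spec.z_planes - 1, z0 + int(rng.integers(1, spec.z_planes)) )
        cell_z[label] = (z0, z1)
        disk = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= r_px ** 2
        for z in range(z0, z1 + 1):
            masks[z][disk] = label

    n_phago = round(spec.n_cells * spec.frac_phagocytic)
    phago_labels = rng.choice(
        np.arange(1, spec.n_cells + 1), size=n_phago, replace=False
    ) if n_phago else np.array([], dtype=int)

    beads: list[list[float]] = []
    bead_labels: list[int] = []
    internal_counts = {lab: 0 for lab in range(1, spec.n_cells + 1)}

    for lab in phago_labels:
        lab = int(lab)
        z0, z1 = cell_z[lab]
        for _ in range(spec.beads_per_phagocytic_cell):
            z = int(rng.integers(z0, z1 + 1))
            inside_y, inside_x = np.nonzero(masks[z] == lab)
            k = int(rng.integers(0, inside_y.size))
            beads.append([
                inside_x[k] * spec.pixel_size_um,
                inside_y[k] * spec.pixel_size_um,
                z * spec.z_step_um,
            ])
            bead_labels.append(lab)
            internal_counts[lab] += 1

    for _ in range(spec.n_external_beads):
        for _ in range(1000):
            z = int(rng.integers(0, spec.z_planes))
            xi = int(rng.integers(0, n_px))
            yi = int(rng.integers(0, n_px))
            if masks[z, yi, xi] == 0:
                beads.append([
                    xi * spec.pixel_size_um, yi * spec.pixel_size_um, z * spec.z_step_um,
                ])
                bead_labels.append(0)
                break
        else:
            raise ValueError("could not place external bead on background")

    scene = CellBeadScene(
        masks=masks,
        bead_xyz_um=np.array(beads, dtype=float).reshape(-1, 3),
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
    )
    return scene, SceneTruth(internal_counts, bead_labels)
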