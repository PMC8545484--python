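"""Two-channel synthetic punctate images with a controlled colocalized fraction.

Puncta are rendered as Gaussian spots on an 8-bit background.  Colocalized
pairs share a centre (offset well below the punctum radius so their
thresholded masks overlap); lone puncta keep a minimum distance from
other-channel puncta so the injected colocalized fraction is exactly the
rendered one.  Same-channel collisions are resolved by rejection sampling
up to a fixed number of attempts, after which a warning flag is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..puncta import ChannelImage

MAX_PLACEMENT_ATTEMPTS = 100


@dataclass(frozen=True)
class PunctaGenSpec:
    fov_um: float = 102.0
    pixel_size_um: float = 0.1
    density_pre_per_100um2: float = 53.0
    density_post_per_100um2: float = 42.0
    density_coloc_per_100um2: float = 26.0
    punctum_diameter_um: float = 0.5
    punctum_intensity: int = 120
    background_level: int = 5
    noise_sd: float = 2.0
    seed: int = 0
    #: minimum centre distance between same- or cross-channel puncta, in
    #: punctum diameters; keeps rendered puncta separable and the injected
    #: colocalized fraction exactly the rendered one
    min_separation_diameters: float = 1.4

    def __post_init__(self) -> None:
        if self.density_coloc_per_100um2 > min(
            self.density_pre_per_100um2, self.density_post_per_100um2
        ):
            raise ValueError("colocalized density cannot exceed either channel density")
        for name in ("punctum_intensity", "background_level"):
            if not 0 <= getattr(self, name) <= 255:
                raise ValueError(f"{name} must be an 8-bit value")
        if not (self.fov_um > 0 and self.pixel_size_um > 0 and self.punctum_diameter_um > 0):
            raise ValueError("geometry parameters must be positive")


@dataclass
class PunctaTruth:
    """Ground truth: centroids (µm) per channel and colocalized index pairs."""

    pre_centroids_um: np.ndarray   # (n_pre, 2)
    post_centroids_um: np.ndarray  # (n_post, 2)
    coloc_pairs: list[tuple[int, int]]  # (pre index, post index)
    packing_warning: bool = False

    @property
    def n_pre(self) -> int:
        return self.pre_centroids_um.shape[0]

    @property
    def n_post(self) -> int:
        return self.post_centroids_um.shape[0]

    @property
    def n_coloc(self) -> int:
        return len(self.coloc_pairs)


class _HardCoreSampler:
    """Uniform placement with a minimum pairwise distance, via a cell grid."""

    def __init__(self, rng: np.random.Generator, fov: float, margin: float, min_dist: float):
        self.rng = rng
        self.fov = fov
        self.margin = margin
        self.min_dist = min_dist
        self.cell = min_dist if min_dist > 0 else fov
        self.grid: dict[tuple[int, int], list[np.ndarray]] = {}

    def _neighbours(self, pt: np.ndarray):
        ci, cj = int(pt[0] // self.cell), int(pt[1] // self.cell)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                yield from self.grid.get((ci + di, cj + dj), ())

    def _clear(self, pt: np.ndarray) -> bool:
        return all(np.hypot(*(q - pt)) >= self.min_dist for q in self._neighbours(pt))

    def register(self, pt: np.ndarray) -> None:
        key = (int(pt[0] // self.cell), int(pt[1] // self.cell))
        self.grid.setdefault(key, []).append(pt)

    def sample(self) -> tuple[np.ndarray | None, bool]:
        """Returns (point or None, hit_attempt_limit flag)."""
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            pt = self.rng.uniform(self.margin, self.fov - self.margin, size=2)
            if self._clear(pt):
                self.register(pt)
                return pt, False
        return None, True


def _render(
    shape: tuple[int, int],
    centers_um: np.ndarray,
    spec: PunctaGenSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian spots + background + noise, clipped to uint8 (no wrap-around)."""
    img = np.full(shape, float(spec.background_level))
    sigma_px = spec.punctum_diameter_um / 4.0 / spec.pixel_size_um
    half = int(np.ceil(4 * sigma_px))
    for cx, cy in centers_um:
        px, py = cx / spec.pixel_size_um, cy / spec.pixel_size_um
        x0 = int(np.floor(px)) - half
        y0 = int(np.floor(py)) - half
        x0c, x1c = max(x0, 0), min(x0 + 2 * half + 1, shape[1])
        y0c, y1c = max(y0, 0), min(y0 + 2 * half + 1, shape[0])
        if x0c >= x1c or y0c >= y1c:
            continue
        gx = np.exp(-0.5 * ((np.arange(x0c, x1c) - px) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((np.arange(y0c, y1c) - py) / sigma_px) ** 2)
        img[y0c:y1c, x0c:x1c] += spec.punctum_intensity * np.outer(gy, gx)
    if spec.noise_sd:
        img += rng.normal(0.0, spec.noise_sd, size=shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def gen_puncta_image(
    spec: PunctaGenSpec,
) -> tuple[ChannelImage, ChannelImage, PunctaTruth]:
    """Simulate a pre/post channel pair; returns (pre, post, ground truth).

    Counts per category are Poisson with mean density × FOV area / 100 µm²
    (lone counts use the density differences, so total channel counts have
    the requested means).  A colocalized pair shares a centre up to a small
    offset; both members are registered against the shared hard-core grid.
    """
    rng = np.random.default_rng(spec.seed)
    area_factor = spec.fov_um ** 2 / 100.0
    n_coloc = rng.poisson(spec.density_coloc_per_100um2 * area_factor)
    n_pre_lone = rng.poisson(
        (spec.density_pre_per_100um2 - spec.density_coloc_per_100um2) * area_factor
    )
    n_post_lone = rng.poisson(
        (spec.density_post_per_100um2 - spec.density_coloc_per_100um2) * area_factor
    )

    min_dist = spec.min_separation_diameters * spec.punctum_diameter_um
    margin = spec.punctum_diameter_um  # keep spots off the image edge
    max_pair_offset = spec.punctum_diameter_um / 8.0
    sampler = _HardCoreSampler(rng, spec.fov_um, margin, min_dist)

    pre_pts: list[np.ndarray] = []
    post_pts: list[np.ndarray] = []
    coloc_pairs: list[tuple[int, int]] = []
    warned = False

    for _ in range(n_coloc):
        center, fail = sampler.sample()
        warned |= fail
        if center is None:
            continue
        angle = rng.uniform(0, 2 * np.pi)
        offset = rng.uniform(0, max_pair_offset)
        delta = offset / 2.0 * np.array([np.cos(angle), np.sin(angle)])
        coloc_pairs.append((len(pre_pts), len(post_pts)))
        pre_pts.append(center - delta)
        post_pts.append(center + delta)

    for target, count in ((pre_pts, n_pre_lone), (post_pts, n_post_lone)):
        for _ in range(count):
            pt, fail = sampler.sample()
            warned |= fail
            if pt is not None:
                target.append(pt)

    def _stacked(pts: list[np.ndarray]) -> np.ndarray:
        return np.vstack(pts) if pts else np.empty((0, 2))

    n_px = int(round(spec.fov_um / spec.pixel_size_um))
    shape = (n_px, n_px)
    pre_img = ChannelImage(
        _render(shape, _stacked(pre_pts), spec, rng), spec.pixel_size_um, "pre"
    )
    post_img = ChannelImage(
        _render(shape, _stacked(post_pts), spec, rng), spec.pixel_size_um, "post"
    )
    truth = PunctaTruth(_stacked(pre_pts), _stacked(post_pts), coloc_pairs, warned)
    return pre_img, post_img, truth
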