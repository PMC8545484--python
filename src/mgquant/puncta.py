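"""Synaptic puncta quantification on two-channel 8-bit images.

Mirrors a standard confocal particle-analysis workflow: rolling-ball
background subtraction, fixed intensity-range thresholding, connected
component labelling with size exclusion, overlap-defined synapse counting,
and engulfment (presynaptic puncta area inside a microglial mask).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import rolling_ball

logger = logging.getLogger(__name__)

# size-exclusion bounds: objects strictly smaller/larger are discarded,
# boundary areas are retained
MIN_AREA_UM2 = 0.05
MAX_AREA_UM2 = 1.2

# 8-connectivity (full 3x3 neighbourhood), matching common particle analysis
_STRUCT_8 = np.ones((3, 3), dtype=bool)


@dataclass
class ChannelImage:
    """A single-channel 2D 8-bit image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be 2-D")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def fov_area_um2(self) -> float:
        return self.pixels.size * self.pixel_size_um ** 2


@dataclass(frozen=True)
class ThresholdSpec:
    """Inclusive 8-bit intensity range used to binarise a channel."""

    low: int
    high: int = 255

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high <= 255):
            raise ValueError("require 0 <= low <= high <= 255")


BASSOON_THRESHOLD = ThresholdSpec(15, 255)
HOMER_THRESHOLD = ThresholdSpec(30, 255)


@dataclass
class Punctum:
    id: int
    pixel_idx: tuple[np.ndarray, np.ndarray]  # (rows, cols)
    area_um2: float
    centroid_um: tuple[float, float]  # (x, y), 0-based pixel-centre convention
    touches_edge: bool = False


@dataclass
class PunctaSet:
    """Size-filtered puncta of one channel, pairwise disjoint by construction."""

    puncta: list[Punctum]
    channel_label: str
    threshold: ThresholdSpec | None
    shape: tuple[int, int]
    pixel_size_um: float

    def __len__(self) -> int:
        return len(self.puncta)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([p.area_um2 for p in self.puncta])

    @property
    def total_area_um2(self) -> float:
        return float(self.areas_um2.sum()) if self.puncta else 0.0

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for p in self.puncta:
            mask[p.pixel_idx] = True
        return mask


@dataclass
class SynapseReport:
    """Counts, densities and area fractions for one image pair."""

    n_pre: int
    n_post: int
    n_synapses: int
    fov_area_um2: float
    area_fraction_pre: float
    area_fraction_post: float
    area_fraction_coloc: float          # intersection pixels / FOV
    area_fraction_coloc_union: float    # union of colocalised puncta / FOV

    def __post_init__(self) -> None:
        if self.n_synapses > min(self.n_pre, self.n_post):
            raise ValueError("n_synapses cannot exceed min(n_pre, n_post)")

    def density_per_mm2(self, count: int | None = None) -> float:
        count = self.n_synapses if count is None else count
        return count / (self.fov_area_um2 / 1e6)

    def density_per_100um2(self, count: int | None = None) -> float:
        count = self.n_synapses if count is None else count
        return count / (self.fov_area_um2 / 100.0)


def subtract_background(img: ChannelImage, radius_px: int = 10) -> ChannelImage:
    """Rolling-ball background subtraction, output clipped to [0, 255].

    The output is pixelwise ≤ the input (the estimated background is
    non-negative).
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    pixels = img.pixels.astype(float)
    background = rolling_ball(pixels, radius=radius_px)
    out = np.clip(pixels - background, 0, 255)
    return ChannelImage(out.astype(img.pixels.dtype), img.pixel_size_um, img.channel_label)


def threshold_channel(img: ChannelImage, spec: ThresholdSpec) -> np.ndarray:
    """Binary mask of pixels with spec.low <= value <= spec.high (inclusive)."""
    return (img.pixels >= spec.low) & (img.pixels <= spec.high)


def _size_keep(area_um2: float) -> bool:
    # relative epsilon so boundary areas survive pixel-area roundoff
    eps = 1e-9
    return MIN_AREA_UM2 * (1 - eps) <= area_um2 <= MAX_AREA_UM2 * (1 + eps)


def find_puncta(
    mask: np.ndarray,
    pixel_size_um: float,
    channel_label: str = "",
    threshold: ThresholdSpec | None = None,
) -> PunctaSet:
    """8-connected components of ``mask``, size-filtered to plausible puncta.

    Components with area below 0.05 µm² or above 1.2 µm² are discarded
    (boundary areas retained).  Puncta touching the image edge are kept and
    flagged.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    labels, n_labels = ndimage.label(mask, structure=_STRUCT_8)
    px_area = pixel_size_um ** 2
    h, w = mask.shape
    puncta: list[Punctum] = []
    if n_labels:
        objects = ndimage.find_objects(labels)
        for lab, sl in enumerate(objects, start=1):
            rows, cols = np.nonzero(labels[sl] == lab)
            rows = rows + sl[0].start
            cols = cols + sl[1].start
            area = rows.size * px_area
            if not _size_keep(area):
                continue
            cx = float(cols.mean()) * pixel_size_um
            cy = float(rows.mean()) * pixel_size_um
            edge = bool(
                rows.min() == 0 or cols.min() == 0
                or rows.max() == h - 1 or cols.max() == w - 1
            )
            puncta.append(Punctum(len(puncta) + 1, (rows, cols), area, (cx, cy), edge))
    return PunctaSet(puncta, channel_label, threshold, mask.shape, pixel_size_um)


def colocalize(pre: PunctaSet, post: PunctaSet) -> SynapseReport:
    """Count synapses as pre puncta overlapping ≥1 pixel of any post punctum.

    A pre punctum overlapping several post puncta counts once.  Both the
    pixel-intersection area fraction and the union-of-colocalised-puncta
    area fraction are reported.
    """
    if pre.shape != post.shape or pre.pixel_size_um != post.pixel_size_um:
        raise ValueError("pre and post sets must share image geometry")
    post_mask = post.to_mask()
    fov_px = pre.shape[0] * pre.shape[1]

    n_synapses = 0
    intersection_px = 0
    union_px = 0
    post_hit = np.zeros(len(post.puncta), dtype=bool)
    for p in pre.puncta:
        overlap = post_mask[p.pixel_idx]
        if overlap.any():
            n_synapses += 1
            intersection_px += int(overlap.sum())
            union_px += p.pixel_idx[0].size
    pre_mask = pre.to_mask()
    for i, q in enumerate(post.puncta):
        if pre_mask[q.pixel_idx].any():
            post_hit[i] = True
            union_px += q.pixel_idx[0].size
    union_px -= intersection_px  # union = |A| + |B| - |A∩B| over colocalised puncta

    fov_um2 = fov_px * pre.pixel_size_um ** 2
    return SynapseReport(
        n_pre=len(pre),
        n_post=len(post),
        n_synapses=n_synapses,
        fov_area_um2=fov_um2,
        area_fraction_pre=pre_mask.sum() / fov_px,
        area_fraction_post=post_mask.sum() / fov_px,
        area_fraction_coloc=intersection_px / fov_px,
        area_fraction_coloc_union=union_px / fov_px,
    )


def engulfment(
    pre: PunctaSet,
    microglia_mask: np.ndarray,
    pixel_size_um: float | None = None,
) -> dict[int, float]:
    """Total presynaptic puncta area (µm²) inside each labelled cell.

    ``microglia_mask`` is either a boolean mask (treated as one cell,
    label 1) or an integer label image.  Returns {cell label: area µm²};
    cells with no overlapping puncta report 0.
    """
    pixel_size_um = pre.pixel_size_um if pixel_size_um is None else pixel_size_um
    mask = np.asarray(microglia_mask)
    if mask.shape != pre.shape:
        raise ValueError("microglia mask must match puncta image geometry")
    if mask.dtype == bool:
        mask = mask.astype(np.int32)
    labels = [int(v) for v in np.unique(mask) if v > 0]
    if not labels:
        warnings.warn("microglia mask is empty; engulfment is 0 for all cells")
        return {}
    px_area = pixel_size_um ** 2
    out = {lab: 0.0 for lab in labels}
    for p in pre.puncta:
        inside = mask[p.pixel_idx]
        for lab in np.unique(inside):
            if lab > 0:
                out[int(lab)] += int((inside == lab).sum()) * px_area
    return out


def area_fraction(obj: PunctaSet | np.ndarray) -> float:
    """Fraction of the imaged area covered by a mask or a puncta set."""
    if isinstance(obj, PunctaSet):
        mask = obj.to_mask()
    else:
        mask = np.asarray(obj, dtype=bool)
    return float(mask.sum()) / mask.size


def analyze_pair(
    pre_img: ChannelImage,
    post_img: ChannelImage,
    pre_threshold: ThresholdSpec = BASSOON_THRESHOLD,
    post_threshold: ThresholdSpec = HOMER_THRESHOLD,
    background_radius_px: int = 10,
) -> tuple[PunctaSet, PunctaSet, SynapseReport]:
    """Full two-channel pipeline: background → threshold → puncta → synapses."""
    pre_sub = subtract_background(pre_img, background_radius_px)
    post_sub = subtract_background(post_img, background_radius_px)
    pre_set = find_puncta(
        threshold_channel(pre_sub, pre_threshold), pre_img.pixel_size_um,
        pre_img.channel_label or "pre", pre_threshold,
    )
    post_set = find_puncta(
        threshold_channel(post_sub, post_threshold), post_img.pixel_size_um,
        post_img.channel_label or "post", post_threshold,
    )
    return pre_set, post_set, colocalize(pre_set, post_set)
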