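"""Mask generation: cell outline, nucleus, cortical ring, centrosome, ROI boxes.

The cell outline is segmented from the average-projected actin signal by
adaptive (local mean) thresholding, keeping the largest connected
component with holes filled.  The cortical ring — the ~2 µm band just
inside the outline — is obtained by eroding the cell mask with a
rasterized disk and subtracting, which implements a constant-thickness
inward walk from the outline.  The centrosome mask comes from the
maximum-projected pericentrin signal.

Protrusion regions arrive as manually drawn ROI boxes; for cells without
protrusions, reference boxes of the same size are drawn at random from
the cortical ring after excluding a dilated-nucleus neighbourhood, so
that sampled regions sit at a comparable distance from the nucleus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .io_core import CellQuantError, Projection, RoiBox


class SegmentationError(CellQuantError):
    pass


@dataclass
class MaskSet:
    """Binary masks for one cell, all on the same pixel grid."""

    cell: np.ndarray
    nucleus: np.ndarray | None = None
    ring: np.ndarray | None = None
    centrosome: np.ndarray | None = None
    boxes: list[RoiBox] = field(default_factory=list)

    def __post_init__(self) -> None:
        shape = self.cell.shape
        for name in ("nucleus", "ring", "centrosome"):
            mask = getattr(self, name)
            if mask is not None and mask.shape != shape:
                raise ValueError(f"{name} mask shape {mask.shape} != cell {shape}")


def disk_footprint(radius_px: int) -> np.ndarray:
    """Rasterized disk: offsets with ``dx**2 + dy**2 <= radius**2``."""
    if radius_px < 1:
        raise ValueError("radius must be >= 1 px")
    return morphology.disk(radius_px)


def _adaptive_mask(
    image: np.ndarray,
    window_px: int | None,
    offset_frac: float,
    expected_diameter_px: int | None,
) -> np.ndarray:
    """Foreground by local-mean threshold: pixel > local_mean + offset."""
    if window_px is None:
        # default window: twice the expected object diameter
        window_px = 2 * (expected_diameter_px or max(image.shape) // 2) + 1
    if window_px % 2 == 0:
        window_px += 1
    span = float(image.max() - image.min())
    offset = offset_frac * span
    local_mean = filters.threshold_local(image, block_size=window_px, method="mean")
    return image > local_mean + offset


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def segment_cell(
    actin_avg: Projection,
    window_px: int | None = None,
    offset_frac: float = 0.05,
    expected_diameter_px: int | None = None,
    closing_radius_px: int = 2,
) -> np.ndarray:
    """Segment the cell outline from the average-projected actin signal.

    Adaptive local-mean thresholding with a window of roughly twice the
    expected cell diameter, followed by morphological closing, hole
    filling and selection of the single largest connected component.

    Raises
    ------
    SegmentationError
        If no foreground survives ("no cell detected").
    """
    image = actin_avg.image
    raw = _adaptive_mask(image, window_px, offset_frac, expected_diameter_px)
    if closing_radius_px > 0:
        raw = morphology.closing(raw, disk_footprint(closing_radius_px))
    raw = ndi.binary_fill_holes(raw)
    mask = _largest_component(raw)
    if not mask.any():
        raise SegmentationError("no cell detected")
    return mask


def segment_nucleus(
    dapi_avg: Projection,
    cell_mask: np.ndarray,
    window_px: int | None = None,
    offset_frac: float = 0.05,
    expected_diameter_px: int | None = None,
    closing_radius_px: int = 2,
) -> np.ndarray:
    """Segment the nucleus from DAPI and intersect with the cell mask."""
    image = dapi_avg.image
    raw = _adaptive_mask(image, window_px, offset_frac, expected_diameter_px)
    if closing_radius_px > 0:
        raw = morphology.closing(raw, disk_footprint(closing_radius_px))
    raw = ndi.binary_fill_holes(raw)
    mask = _largest_component(raw) & cell_mask
    mask = _largest_component(mask)
    if not mask.any():
        raise SegmentationError("no nucleus detected")
    return mask


def cortical_ring(
    cell_mask: np.ndarray,
    pixel_size_um: float,
    thickness_um: float = 2.0,
    method: str = "erosion",
) -> np.ndarray:
    """Constant-thickness cortical band just inside the cell outline.

    ``ring = cell − erode(cell, disk(round(thickness_um / pixel_size_um)))``
    by default; ``method='edt'`` instead keeps cell pixels whose Euclidean
    distance to the background is at most the thickness (the two agree
    within a pixel of band width).

    Raises
    ------
    SegmentationError
        If the thickness rounds to zero pixels, or the cell is smaller
        than the erosion radius (the ring would swallow the whole cell),
        or the cell mask is empty.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise SegmentationError("empty cell mask")
    radius_px = round(thickness_um / pixel_size_um)
    if radius_px < 1:
        raise SegmentationError(
            f"ring thickness {thickness_um} um rounds to 0 px at "
            f"{pixel_size_um} um/px"
        )
    if method == "erosion":
        eroded = morphology.erosion(cell_mask, disk_footprint(radius_px))
    elif method == "edt":
        eroded = ndi.distance_transform_edt(cell_mask) > radius_px
    else:
        raise ValueError(f"unknown ring method {method!r}")
    if not eroded.any():
        raise SegmentationError(
            f"cell smaller than erosion radius ({radius_px} px); no interior left"
        )
    return cell_mask & ~eroded


def centrosome_mask(
    pcnt_max: Projection,
    threshold: float | None = None,
    min_area_px: int = 4,
) -> np.ndarray:
    """Threshold the maximum-projected pericentrin signal into foci.

    ``threshold=None`` uses Otsu's method within the image.  Small
    components below ``min_area_px`` are removed.  An empty mask is a
    valid result (cells without centrosomes exist, e.g. after PLK4
    inhibition), so no error is raised for blank images.
    """
    image = pcnt_max.image
    if threshold is None:
        if np.ptp(image) == 0:
            return np.zeros(image.shape, dtype=bool)
        threshold = filters.threshold_otsu(image)
    mask = image > threshold
    mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    return mask


def apply_protrusion_boxes(ring_mask: np.ndarray, boxes: list[RoiBox]) -> np.ndarray:
    """Union of (box ∩ ring) over manually drawn protrusion boxes.

    Boxes that miss the ring entirely trigger a warning; an empty union
    is an error.
    """
    ring_mask = np.asarray(ring_mask, dtype=bool)
    region = np.zeros_like(ring_mask)
    for box in boxes:
        if not box.inside(ring_mask.shape):
            raise ValueError(f"box {box} outside image of shape {ring_mask.shape}")
        part = box.to_mask(ring_mask.shape) & ring_mask
        if not part.any():
            warnings.warn(f"box {box} does not intersect the cortical ring")
        region |= part
    if not region.any():
        raise SegmentationError("no protrusion box intersects the cortical ring")
    return region


def select_random_boxes(
    ring_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    box_size_px: int,
    pixel_size_um: float,
    n: int = 2,
    dilation_um: float = 2.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[RoiBox]:
    """Draw ``n`` non-overlapping random cortical boxes for a cell.

    The nucleus is first dilated (default by the ring thickness, 2 µm)
    and removed from the ring so that sampled regions sit at a distance
    from the nucleus comparable to true protrusions.  Box centres are
    then drawn by seeded rejection sampling from the remaining eligible
    ring pixels; boxes must lie inside the image and be pairwise
    non-overlapping.  Deterministic given ``seed``.
    """
    ring_mask = np.asarray(ring_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    dil_px = round(dilation_um / pixel_size_um)
    if dil_px >= 1 and nucleus_mask.any():
        dilated = morphology.dilation(nucleus_mask, disk_footprint(dil_px))
    else:
        dilated = nucleus_mask
    eligible = ring_mask & ~dilated
    ys, xs = np.nonzero(eligible)
    if ys.size == 0:
        raise SegmentationError("no eligible cortical region after nucleus dilation")

    rng = np.random.default_rng(seed)
    h, w = ring_mask.shape
    half_lo = box_size_px // 2
    half_hi = box_size_px - half_lo
    placed: list[RoiBox] = []
    attempts = 0
    while len(placed) < n and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(ys.size))
        cy, cx = int(ys[i]), int(xs[i])
        x0, x1 = cx - half_lo, cx + half_hi
        y0, y1 = cy - half_lo, cy + half_hi
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            continue
        box = RoiBox(x0=x0, y0=y0, x1=x1, y1=y1, label="random")
        if any(box.overlaps(other) for other in placed):
            continue
        placed.append(box)
    if len(placed) < n:
        raise SegmentationError(
            f"could only place {len(placed)}/{n} non-overlapping boxes "
            f"after {max_attempts} attempts"
        )
    return placed


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)
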