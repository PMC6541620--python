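"""Regional intensity measurements, ratios and colocalization.

All intensity measurements are taken on the maximum projection of the
protein-of-interest channel under masks derived from the segmentation
signals: mean intensity under the cortical region (protrusion boxes or
random boxes), total intensity under the centrosome mask, and the
nuclear-to-cytoplasmic ratio (cytoplasm = whole cell minus nucleus).
Per-experiment normalisation divides by the mean of the control cells of
the same batch, so control folds average to exactly 1 per batch.

Colocalization is the Pearson correlation of two channels over the
combined (union) foreground masks of both channels, normalised by a
self-reference coefficient — one signal detected with two differently
labelled secondary antibodies — so that perfect colocalization at the
achievable registration limit maps to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import filters

from .io_core import CellQuantError, Projection, RoiBox

REGIONS = (
    "cortex_protrusion",
    "cortex_random",
    "centrosome",
    "nucleus",
    "cytoplasm",
    "whole_cell",
)


class QuantificationError(CellQuantError):
    pass


@dataclass(frozen=True)
class QuantRecord:
    """One regional measurement for one cell."""

    cell_id: str
    condition: str
    batch: str
    region: str
    poi: str
    raw: float
    normalized: float | None = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.raw < 0:
            raise ValueError("raw intensity must be >= 0")


@dataclass(frozen=True)
class ColocResult:
    """Observed, reference and normalised colocalization coefficients."""

    r_obs: float
    r_ref: float | None = None
    r_norm: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r_obs <= 1.0 + 1e-12:
            raise ValueError(f"correlation out of range: {self.r_obs}")


def _region_to_mask(
    region: np.ndarray | Sequence[RoiBox], shape_yx: tuple[int, int]
) -> np.ndarray:
    if isinstance(region, np.ndarray):
        return region.astype(bool)
    mask = np.zeros(shape_yx, dtype=bool)
    for box in region:
        mask |= box.to_mask(shape_yx)
    return mask


def mean_intensity(
    region: np.ndarray | Sequence[RoiBox], poi_max: Projection
) -> float:
    """Arithmetic mean of POI pixels under a mask or a set of ROI boxes."""
    mask = _region_to_mask(region, poi_max.image.shape)
    if not mask.any():
        raise QuantificationError("empty measurement region")
    return float(poi_max.image[mask].mean())


def centrosome_total_intensity(
    centrosome_mask: np.ndarray, poi_max: Projection
) -> float:
    """Total POI intensity under the centrosome mask; 0 for an empty mask."""
    mask = centrosome_mask.astype(bool)
    if not mask.any():
        return 0.0
    return float(poi_max.image[mask].sum())


def nc_ratio(
    nucleus_mask: np.ndarray, cell_mask: np.ndarray, poi_max: Projection
) -> float:
    """Mean nuclear / mean cytoplasmic POI intensity.

    Cytoplasm is the whole cell excluding the nucleus region.
    """
    nucleus = nucleus_mask.astype(bool)
    cell = cell_mask.astype(bool)
    cytoplasm = cell & ~nucleus
    if not nucleus.any():
        raise QuantificationError("empty nucleus mask")
    if not cytoplasm.any():
        raise QuantificationError("empty cytoplasm (nucleus covers the whole cell)")
    cyt_mean = float(poi_max.image[cytoplasm].mean())
    if cyt_mean == 0:
        raise QuantificationError("zero cytoplasmic mean; ratio undefined")
    return float(poi_max.image[nucleus].mean()) / cyt_mean


def aspect_ratio(cell_mask: np.ndarray) -> float:
    """Major/minor axis ratio of the mask's best-fit ellipse (second moments).

    Pixels are treated as unit squares (each contributes 1/12 to the
    per-axis variance), so an axis-aligned w x h pixel rectangle yields
    exactly w/h and a rasterized disk yields ~1.  Always >= 1.
    """
    mask = np.asarray(cell_mask, dtype=bool)
    n = mask.sum()
    if n == 0:
        raise QuantificationError("empty mask")
    if n == 1:
        raise QuantificationError("degenerate single-pixel mask")
    ys, xs = np.nonzero(mask)
    xc, yc = xs.mean(), ys.mean()
    dx, dy = xs - xc, ys - yc
    cxx = (dx * dx).mean() + 1.0 / 12.0
    cyy = (dy * dy).mean() + 1.0 / 12.0
    cxy = (dx * dy).mean()
    tr, det = cxx + cyy, cxx * cyy - cxy * cxy
    disc = max(tr * tr / 4 - det, 0.0)
    lam1 = tr / 2 + np.sqrt(disc)
    lam2 = tr / 2 - np.sqrt(disc)
    return float(np.sqrt(lam1 / lam2))


def normalize_to_control(
    records: pd.DataFrame | Sequence[QuantRecord],
    control_condition: str,
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Add per-batch control-normalised folds to measurement records.

    ``fold = raw / mean(raw over control cells of the same batch)``, so
    control folds average to exactly 1 within each batch.  Records of
    different measurement types are normalised separately: grouping is
    by batch plus any of the ``region``/``poi`` columns present.  Every
    group must contain at least one control cell.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame([r.__dict__ for r in records])
    df = records.copy()
    keys = [batch_col] + [c for c in ("region", "poi") if c in df.columns]
    out = []
    for group_key, sub in df.groupby(keys, sort=False):
        ctrl = sub.loc[sub["condition"] == control_condition, "raw"]
        if ctrl.empty:
            raise QuantificationError(
                f"group {group_key!r} has no cells with control condition "
                f"{control_condition!r}"
            )
        ctrl_mean = ctrl.mean()
        if ctrl_mean == 0:
            raise QuantificationError(f"group {group_key!r}: zero control mean")
        sub = sub.assign(normalized=sub["raw"] / ctrl_mean)
        out.append(sub)
    return pd.concat(out).loc[df.index]


def coloc_coefficient(
    crop_ch1: np.ndarray,
    crop_ch2: np.ndarray,
    mask_method: str = "otsu",
    combine: str = "union",
) -> ColocResult:
    """Mask-based Pearson colocalization of two channel crops.

    Foreground masks are built per channel (Otsu threshold within the
    crop by default) and combined — union by default, so signal present
    in either channel contributes; intersection is available.  The
    Pearson correlation of the two channels over the combined mask takes
    both overlap and intensity covariation into account.
    """
    a = np.asarray(crop_ch1, dtype=float)
    b = np.asarray(crop_ch2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"crop shapes differ: {a.shape} vs {b.shape}")

    def fg(img: np.ndarray) -> np.ndarray:
        if mask_method == "otsu":
            if np.ptp(img) == 0:
                return np.zeros(img.shape, dtype=bool)
            return img > filters.threshold_otsu(img)
        if mask_method == "none":
            return np.ones(img.shape, dtype=bool)
        raise ValueError(f"unknown mask method {mask_method!r}")

    m1, m2 = fg(a), fg(b)
    if combine == "union":
        mask = m1 | m2
    elif combine == "intersection":
        mask = m1 & m2
    else:
        raise ValueError(f"unknown combine mode {combine!r}")
    if not mask.any():
        raise QuantificationError("combined colocalization mask is empty")
    x, y = a[mask], b[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise QuantificationError(
            "constant channel under the combined mask; correlation undefined"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    return ColocResult(r_obs=r)


def coloc_normalized(result: ColocResult, reference: ColocResult) -> ColocResult:
    """Normalise an observed coefficient by the self-reference coefficient."""
    r_ref = reference.r_obs
    if r_ref is None or r_ref <= 0:
        raise QuantificationError(f"non-positive reference coefficient: {r_ref}")
    return replace(result, r_ref=r_ref, r_norm=result.r_obs / r_ref)
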