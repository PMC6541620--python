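"""Scratch-wound closure quantification.

The wound is the smooth, cell-free band in a phase-contrast frame: cells
form a high-variance texture while the scratch is locally flat, so the
wound is segmented by thresholding the local standard deviation in a
sliding window and keeping the largest smooth component.  Closure is
reported as residual area — wound area at time t as a percent of the
area at t = 0 — and its complement, area recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from .io_core import CellQuantError


class WoundError(CellQuantError):
    pass


@dataclass(frozen=True)
class WoundMeasurement:
    area_px2: float
    area_um2: float
    mask: np.ndarray


@dataclass(frozen=True)
class WoundSeries:
    """Residual/recovered wound area over time, relative to t = 0."""

    timepoints_h: np.ndarray
    area_um2: np.ndarray
    residual_pct: np.ndarray
    recovered_pct: np.ndarray

    def __post_init__(self) -> None:
        for name in ("timepoints_h", "area_um2", "residual_pct", "recovered_pct"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(self.area_um2 < 0):
            raise ValueError("areas must be >= 0")


def local_std(image: np.ndarray, window_px: int = 7) -> np.ndarray:
    """Sliding-window standard deviation (uniform window, reflect edges)."""
    img = np.asarray(image, dtype=float)
    m = ndi.uniform_filter(img, size=window_px, mode="reflect")
    m2 = ndi.uniform_filter(img * img, size=window_px, mode="reflect")
    return np.sqrt(np.clip(m2 - m * m, 0, None))


def wound_area(
    frame: np.ndarray,
    pixel_size_um: float,
    window_px: int = 7,
    std_threshold: float | None = 5.0,
    min_area_px: int = 64,
) -> WoundMeasurement:
    """Segment and measure the cell-free wound region of one frame.

    Pixels whose local standard deviation falls below ``std_threshold``
    (Otsu on the local-std image when ``None``) are wound candidates;
    after morphological opening, the largest candidate component is the
    wound.  An area of zero (confluent frame) is a valid result.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2D")
    sd = local_std(frame, window_px)
    if std_threshold is None:
        if np.ptp(sd) == 0:
            return _measure(np.ones(frame.shape, dtype=bool), pixel_size_um)
        std_threshold = float(filters.threshold_otsu(sd))
    smooth = sd < std_threshold
    smooth = morphology.opening(smooth, morphology.disk(max(1, window_px // 3)))
    smooth = morphology.remove_small_objects(smooth, max_size=min_area_px - 1)
    labels, n = ndi.label(smooth)
    if n == 0:
        return _measure(np.zeros(frame.shape, dtype=bool), pixel_size_um)
    sizes = ndi.sum_labels(smooth, labels, index=np.arange(1, n + 1))
    wound = labels == (int(np.argmax(sizes)) + 1)
    return _measure(wound, pixel_size_um)


def _measure(mask: np.ndarray, pixel_size_um: float) -> WoundMeasurement:
    area_px2 = float(mask.sum())
    return WoundMeasurement(
        area_px2=area_px2, area_um2=area_px2 * pixel_size_um**2, mask=mask
    )


def residual_series(
    areas_um2: "np.ndarray | list[float]",
    timepoints_h: "np.ndarray | list[float]",
) -> WoundSeries:
    """Express wound areas as percent residual (and recovered) of t = 0."""
    areas = np.asarray(areas_um2, dtype=float)
    times = np.asarray(timepoints_h, dtype=float)
    if areas.size != times.size:
        raise ValueError("areas and timepoints differ in length")
    if areas.size == 0:
        raise WoundError("empty series")
    if areas[0] <= 0:
        raise WoundError("no wound detected at t = 0; residual undefined")
    residual = 100.0 * areas / areas[0]
    return WoundSeries(
        timepoints_h=times,
        area_um2=areas,
        residual_pct=residual,
        recovered_pct=100.0 - residual,
    )
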