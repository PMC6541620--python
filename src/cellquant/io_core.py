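"""Input/output and core containers for the quantification pipeline.

Conventions used throughout the package:

* image stacks are indexed ``(channel, z, y, x)``;
* pixel coordinates are 0-based; ROI boxes are half-open
  ``[x0, x1) x [y0, y1)``;
* physical distances are in micrometres, derived from an isotropic
  ``pixel_size_um``;
* time is stored in hours; frame indices in track tables are converted
  with a configured frame interval (default 10 minutes).

Deconvolution is out of scope: the pipeline consumes raw or
already-deconvolved stacks as written by the acquisition software.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: channel roles understood by the pipeline
ROLES = ("actin", "dapi", "pcnt", "poi", "poi2")

#: default frame interval for track tables given as frame indices (10 min)
DEFAULT_FRAME_INTERVAL_H = 1.0 / 6.0


class CellQuantError(Exception):
    """Base class for errors raised by this package."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageStack:
    """Multi-channel, multi-plane fluorescence volume.

    Parameters
    ----------
    data:
        Intensity array indexed ``(channel, z, y, x)``; finite and
        non-negative.
    pixel_size_um:
        Isotropic x/y pixel size in micrometres (strictly positive).
    channel_map:
        Mapping from channel role (one of :data:`ROLES`) to channel index.
    """

    data: np.ndarray
    pixel_size_um: float
    channel_map: Mapping[str, int]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"stack must be (channel, z, y, x); got ndim={data.ndim}")
        if not np.all(np.isfinite(data)):
            raise ValueError("stack contains non-finite values")
        if np.any(data < 0):
            raise ValueError("stack contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be > 0; got {self.pixel_size_um}")
        for role, idx in self.channel_map.items():
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}; valid roles: {ROLES}")
            if not 0 <= idx < data.shape[0]:
                raise ValueError(
                    f"channel_map[{role!r}] = {idx} out of range for "
                    f"{data.shape[0]}-channel stack"
                )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_map", dict(self.channel_map))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(z, y, x)`` sub-volume for a channel role."""
        if role not in self.channel_map:
            raise KeyError(f"role {role!r} not in channel_map {sorted(self.channel_map)}")
        return self.data[self.channel_map[role]]


@dataclass(frozen=True)
class Projection:
    """A 2D z-projection of one channel of a stack."""

    image: np.ndarray
    method: str
    source_role: str

    def __post_init__(self) -> None:
        image = np.asarray(self.image, dtype=float)
        if image.ndim != 2:
            raise ValueError("projection image must be 2D")
        if self.method not in ("max", "average"):
            raise ValueError(f"unknown projection method {self.method!r}")
        object.__setattr__(self, "image", image)


@dataclass(frozen=True)
class RoiBox:
    """Axis-aligned pixel box, 0-based, half-open ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int
    label: str = "random"

    def __post_init__(self) -> None:
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate box {self}")
        if self.label not in ("protrusion", "random"):
            raise ValueError(f"unknown box label {self.label!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def slices(self) -> tuple[slice, slice]:
        """(row, column) slices selecting the box in an image array."""
        return slice(self.y0, self.y1), slice(self.x0, self.x1)

    def inside(self, shape_yx: tuple[int, int]) -> bool:
        h, w = shape_yx
        return 0 <= self.x0 and 0 <= self.y0 and self.x1 <= w and self.y1 <= h

    def overlaps(self, other: "RoiBox") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )

    def to_mask(self, shape_yx: tuple[int, int]) -> np.ndarray:
        if not self.inside(shape_yx):
            raise ValueError(f"box {self} outside image of shape {shape_yx}")
        mask = np.zeros(shape_yx, dtype=bool)
        mask[self.slices] = True
        return mask


@dataclass(frozen=True)
class Track:
    """Time-ordered 2D positions of one cell centre.

    Times are in hours on a uniform grid; coordinates in micrometres.
    """

    track_id: str
    times: np.ndarray
    xs: np.ndarray
    ys: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        xs = np.asarray(self.xs, dtype=float)
        ys = np.asarray(self.ys, dtype=float)
        if times.size < 2:
            raise ValueError(f"track {self.track_id!r} has fewer than 2 points")
        if not (times.size == xs.size == ys.size):
            raise ValueError(f"track {self.track_id!r}: times/xs/ys length mismatch")
        for name, arr in (("times", times), ("xs", xs), ("ys", ys)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"track {self.track_id!r}: non-finite {name}")
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise ValueError(f"track {self.track_id!r}: times not strictly increasing")
        dt = float(np.median(dts))
        if np.any(np.abs(dts - dt) > 1e-6 + 1e-4 * dt):
            raise ValueError(f"track {self.track_id!r}: non-uniform time spacing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "xs", xs)
        object.__setattr__(self, "ys", ys)

    @property
    def dt_h(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_points(self) -> int:
        return int(self.times.size)

    @property
    def positions(self) -> np.ndarray:
        """``(n, 2)`` array of (x, y) positions in micrometres."""
        return np.column_stack([self.xs, self.ys])


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def read_image_stack(
    path: str | Path,
    channel_map: Mapping[str, int],
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF into an :class:`ImageStack`.

    Axis handling: a 4D file is taken as ``(channel, z, y, x)``, a 3D file
    as ``(channel, y, x)`` with a single z-plane, and a 2D file as a
    single-channel single-plane image.  The pixel size is taken from TIFF
    resolution metadata when present; otherwise ``pixel_size_um`` is used
    as a fall-back (with a logged warning).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
    if arr.ndim == 2:
        arr = arr[np.newaxis, np.newaxis]
    elif arr.ndim == 3:
        arr = arr[:, np.newaxis]
    elif arr.ndim != 4:
        raise ValueError(f"{path}: cannot interpret array of ndim {arr.ndim} as a stack")

    if meta_px is not None:
        px = meta_px
    elif pixel_size_um is not None:
        logger.warning(
            "%s: no pixel size in metadata; falling back to configured %.4f um",
            path,
            pixel_size_um,
        )
        px = pixel_size_um
    else:
        raise ValueError(f"{path}: no pixel size in metadata and no fall-back given")
    return ImageStack(data=arr.astype(float), pixel_size_um=px, channel_map=channel_map)


def _pixel_size_from_tiff(tif: "tifffile.TiffFile") -> float | None:
    page = tif.pages[0]
    tag = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if tag is None or unit is None:
        return None
    num, den = tag.value
    if num == 0:
        return None
    # pixels per unit -> um per pixel
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(getattr(unit.value, "value", unit.value)))
    if unit_um is None:
        return None
    return float(den) / float(num) * unit_um


def write_image_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` to TIFF with resolution metadata (cm)."""
    ppcm = 10000.0 / stack.pixel_size_um
    tifffile.imwrite(
        Path(path),
        stack.data.astype(np.float32),
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
        photometric="minisblack",
    )


def project(stack: ImageStack, role: str, method: str) -> Projection:
    """Project one channel over z by pixelwise maximum or arithmetic mean.

    The maximum projection is used for the protein-of-interest signal and
    the average projection for segmentation signals (actin, DAPI).
    """
    vol = stack.channel(role)
    if method == "max":
        image = vol.max(axis=0)
    elif method == "average":
        image = vol.mean(axis=0)
    else:
        raise ValueError(f"unknown projection method {method!r}; use 'max' or 'average'")
    return Projection(image=image, method=method, source_role=role)


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------


def read_tracks(
    path: str | Path,
    frame_interval_h: float = DEFAULT_FRAME_INTERVAL_H,
) -> list[Track]:
    """Read a track table (CSV) into a list of :class:`Track`.

    Expected columns: ``track_id``, ``x_um``, ``y_um`` and either
    ``time_h`` (hours) or ``frame`` (0-based index, converted with
    ``frame_interval_h``).  Rows may appear in any order; duplicated
    (track, time) rows are an error.
    """
    df = pd.read_csv(path)
    required = {"track_id", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "time_h" in df.columns:
        df = df.assign(_t=df["time_h"].astype(float))
    elif "frame" in df.columns:
        df = df.assign(_t=df["frame"].astype(float) * frame_interval_h)
    else:
        raise ValueError(f"{path}: need a 'time_h' or 'frame' column")

    tracks: list[Track] = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("_t")
        if sub["_t"].duplicated().any():
            raise ValueError(f"track {tid!r}: duplicated time points")
        tracks.append(
            Track(
                track_id=str(tid),
                times=sub["_t"].to_numpy(),
                xs=sub["x_um"].to_numpy(float),
                ys=sub["y_um"].to_numpy(float),
            )
        )
    return tracks


def write_tracks(tracks: Iterable[Track], path: str | Path) -> None:
    """Write tracks to CSV with columns track_id, time_h, x_um, y_um."""
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.times, tr.xs, tr.ys):
            rows.append({"track_id": tr.track_id, "time_h": t, "x_um": x, "y_um": y})
    pd.DataFrame(rows, columns=["track_id", "time_h", "x_um", "y_um"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# ROI boxes
# ---------------------------------------------------------------------------

_BOX_COLUMNS = ["x0", "y0", "x1", "y1", "label"]


def read_roi_boxes(path: str | Path) -> list[RoiBox]:
    """Read ROI boxes from CSV (columns x0,y0,x1,y1,label) or a JSON list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict("records")
    boxes = []
    for rec in records:
        boxes.append(
            RoiBox(
                x0=int(rec["x0"]),
                y0=int(rec["y0"]),
                x1=int(rec["x1"]),
                y1=int(rec["y1"]),
                label=str(rec.get("label", "random")),
            )
        )
    return boxes


def write_roi_boxes(boxes: Sequence[RoiBox], path: str | Path) -> None:
    path = Path(path)
    records = [
        {"x0": b.x0, "y0": b.y0, "x1": b.x1, "y1": b.y1, "label": b.label} for b in boxes
    ]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2))
    else:
        pd.DataFrame(records, columns=_BOX_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tabular results
# ---------------------------------------------------------------------------

#: stable long-format schema for quantification records
RECORD_COLUMNS = [
    "cell_id",
    "condition",
    "batch",
    "region",
    "poi",
    "raw",
    "normalized",
]


def write_records(records, path: str | Path) -> None:
    """Write measurement records as long-format CSV with a stable schema.

    ``records`` may be a DataFrame, a list of dicts, or a list of
    dataclass instances with the fields of :data:`RECORD_COLUMNS`.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for rec in records:
            if hasattr(rec, "__dataclass_fields__"):
                rows.append({k: getattr(rec, k) for k in rec.__dataclass_fields__})
            else:
                rows.append(dict(rec))
        df = pd.DataFrame(rows, columns=RECORD_COLUMNS if not rows else None)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[RECORD_COLUMNS]
    df.to_csv(path, index=False)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
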