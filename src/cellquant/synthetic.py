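"""Synthetic ground-truth generators: cell phantoms, trajectories, wounds.

Every generator is a pure function of its spec (including the seed), so
identical specs give bit-identical output.  The phantoms emulate the
statistical structure the quantification assumes — a bright actin
outline, a DAPI nucleus, punctate pericentrin foci, and a
protein-of-interest (POI) channel with a prescribed cortical enrichment
fold ``E`` and nuclear-to-cytoplasmic ratio ``rho`` — with known masks
returned alongside, so segmentation and intensity measurements can be
validated against exact truth.

Piecewise-constant POI levels are solved so that *both* ratios hold
exactly on the true masks:

* ``E = mean(ring) / mean(interior)`` with interior = cell − ring,
* ``rho = mean(nucleus) / mean(cytoplasm)`` with cytoplasm = cell − nucleus.

Because the ring is part of the cytoplasm and the nucleus part of the
interior, the ring and nucleus levels are coupled linearly and solved
jointly (see :func:`_solve_poi_levels`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_core import ImageStack, Track
from .segmentation import cortical_ring

DEFAULT_CHANNEL_MAP = {"actin": 0, "dapi": 1, "pcnt": 2, "poi": 3}

#: baseline cytoplasmic POI level (arbitrary units); noise fractions refer to it
_BASE_LEVEL = 100.0
_BACKGROUND = 10.0


@dataclass
class GroundTruth:
    """Known truth accompanying a synthetic dataset."""

    masks: dict[str, np.ndarray] | None = None
    enrichment: float | None = None
    nc_ratio: float | None = None
    track_params: dict | None = None
    wound_areas_um2: list[float] | None = None


# ---------------------------------------------------------------------------
# cell phantoms
# ---------------------------------------------------------------------------


@dataclass
class CellPhantomSpec:
    """Geometry, intensity and noise parameters of one cell phantom.

    ``cortical_enrichment_fold`` (E) and ``nc_ratio`` (rho) are the two
    quantities the intensity pipeline is meant to recover.  Lengths are
    in micrometres; the image is square with isotropic pixels.
    """

    image_size_px: int = 192
    pixel_size_um: float = 0.2
    n_z: int = 1
    cell_radius_um: float = 12.0
    n_protrusions: int = 0
    protrusion_length_um: float = 6.0
    protrusion_width_um: float = 2.5
    nucleus_radius_um: float = 5.0
    nucleus_offset_um: float = 0.0
    ring_thickness_um: float = 2.0
    cortical_enrichment_fold: float = 2.0
    nc_ratio: float = 0.65
    centrosome_foci: Sequence[tuple[float, float, float, float]] = (
        (6.0, 0.0, 400.0, 0.25),
    )
    background: float = _BACKGROUND
    noise_model: str = "gaussian"
    noise_sd_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cortical_enrichment_fold <= 0:
            raise ValueError("cortical enrichment fold must be > 0")
        if self.nc_ratio <= 0:
            raise ValueError("nc_ratio must be > 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        half_um = self.image_size_px * self.pixel_size_um / 2
        reach = self.cell_radius_um + (
            self.protrusion_length_um if self.n_protrusions else 0.0
        )
        if reach >= half_um - 2 * self.pixel_size_um:
            raise ValueError("cell (with protrusions) does not fit in the image")
        if self.nucleus_offset_um + self.nucleus_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus does not fit inside the cell")


def _grid_um(spec: CellPhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    n = spec.image_size_px
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    return (xx - c) * spec.pixel_size_um, (yy - c) * spec.pixel_size_um


def _cell_mask(spec: CellPhantomSpec) -> np.ndarray:
    xu, yu = _grid_um(spec)
    mask = xu**2 + yu**2 <= spec.cell_radius_um**2
    if spec.n_protrusions > 0:
        rng = np.random.default_rng(spec.seed + 1)
        # evenly spaced arms with a seeded phase, as capsules along radii
        phase = rng.uniform(0, 2 * np.pi)
        for k in range(spec.n_protrusions):
            theta = phase + 2 * np.pi * k / spec.n_protrusions
            ux, uy = np.cos(theta), np.sin(theta)
            t = xu * ux + yu * uy  # coordinate along the arm axis
            d = np.abs(-xu * uy + yu * ux)  # distance from the axis
            tip = spec.cell_radius_um + spec.protrusion_length_um
            arm = (t >= 0) & (t <= tip) & (d <= spec.protrusion_width_um / 2)
            cap = (xu - tip * ux) ** 2 + (yu - tip * uy) ** 2 <= (
                spec.protrusion_width_um / 2
            ) ** 2
            mask |= arm | cap
    return mask


def _solve_poi_levels(
    n_ring: int, n_inner: int, n_nucleus: int, enrichment: float, nc_ratio: float
) -> tuple[float, float, float]:
    """Piecewise-constant POI levels (ring, inner cytoplasm, nucleus).

    Solves the 2x2 linear system so that mean(ring)/mean(cell − ring) = E
    and mean(nucleus)/mean(cell − nucleus) = rho simultaneously, with the
    inner-cytoplasm level fixed at the base level.
    """
    a, b, m = float(n_ring), float(n_inner), float(n_nucleus)
    i_v = _BASE_LEVEL
    denom = (m + b) * (a + b) - enrichment * m * nc_ratio * a
    if denom <= 0:
        raise ValueError(
            "enrichment/nc_ratio combination has no positive-intensity solution "
            "for this geometry"
        )
    r_v = enrichment * i_v * b * (m * nc_ratio + a + b) / denom
    n_v = nc_ratio * (a * r_v + b * i_v) / (a + b)
    if r_v <= 0 or n_v <= 0:
        raise ValueError("solved POI levels are non-positive")
    return r_v, i_v, n_v


def make_cell_image(spec: CellPhantomSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a 4-channel phantom and return it with its ground truth.

    Channels: actin (bright cortical band over a dimmer fill), DAPI
    (nucleus), PCNT (Gaussian foci), POI (levels solved for the requested
    enrichment and N/C ratio).  The truth ring is the cortical band of
    the *true* cell mask at the spec thickness, built with the same
    inward-walk construction the segmentation stage uses.
    """
    xu, yu = _grid_um(spec)
    cell = _cell_mask(spec)
    nucleus = (xu - spec.nucleus_offset_um) ** 2 + yu**2 <= spec.nucleus_radius_um**2
    ring = cortical_ring(cell, spec.pixel_size_um, spec.ring_thickness_um)
    if (nucleus & ring).any():
        raise ValueError("nucleus touches the cortical ring; shrink or recentre it")

    inner = cell & ~ring & ~nucleus
    r_v, i_v, n_v = _solve_poi_levels(
        int(ring.sum()),
        int(inner.sum()),
        int(nucleus.sum()),
        spec.cortical_enrichment_fold,
        spec.nc_ratio,
    )

    bg = spec.background
    poi = np.full(cell.shape, bg)
    poi[inner] = i_v
    poi[ring] = r_v
    poi[nucleus] = n_v

    actin = np.full(cell.shape, bg)
    actin[cell] = 0.6 * _BASE_LEVEL
    actin[ring] = 1.5 * _BASE_LEVEL

    dapi = np.full(cell.shape, bg)
    dapi[nucleus] = 1.5 * _BASE_LEVEL

    pcnt = np.full(cell.shape, bg)
    centrosome = np.zeros(cell.shape, dtype=bool)
    for fx, fy, amp, sigma_um in spec.centrosome_foci:
        d2 = (xu - fx) ** 2 + (yu - fy) ** 2
        pcnt += amp * np.exp(-d2 / (2 * sigma_um**2))
        centrosome |= d2 <= (2 * max(sigma_um, spec.pixel_size_um)) ** 2

    planes = np.stack([actin, dapi, pcnt, poi])  # (4, y, x)
    stack = np.repeat(planes[:, np.newaxis], spec.n_z, axis=1)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_model == "gaussian" and spec.noise_sd_frac > 0:
        stack = stack + rng.normal(0, spec.noise_sd_frac * _BASE_LEVEL, stack.shape)
    elif spec.noise_model == "poisson":
        stack = rng.poisson(stack).astype(float)
    stack = np.clip(stack, 0, None)

    truth = GroundTruth(
        masks={"cell": cell, "nucleus": nucleus, "ring": ring, "centrosome": centrosome},
        enrichment=spec.cortical_enrichment_fold,
        nc_ratio=spec.nc_ratio,
    )
    image = ImageStack(
        data=stack, pixel_size_um=spec.pixel_size_um, channel_map=DEFAULT_CHANNEL_MAP
    )
    return image, truth


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

TRACK_MODELS = ("random_walk", "ballistic", "persistent", "decaying_speed")


@dataclass
class TrajectorySpec:
    """Parameters of a 2D trajectory ensemble.

    Defaults mirror the standard live-imaging protocol: positions every
    10 minutes for 16 hours, 40 cells per condition.  ``diffusion`` is
    the 2D diffusion coefficient D (MSD slope 4D) of the random walk;
    ``speed`` drives the ballistic and persistent models; the
    decaying-speed model interpolates from ``s0`` to ``s_inf`` with a
    base-2 exponential so ``half_life_h`` is the literal half-life.
    """

    model: str = "random_walk"
    dt_h: float = 1.0 / 6.0
    duration_h: float = 16.0
    n_tracks: int = 40
    diffusion_um2_per_h: float = 37.5
    speed_um_per_h: float = 30.0
    persistence: float = 0.7
    s0_um_per_h: float = 30.0
    s_inf_um_per_h: float = 3.0
    half_life_h: float = 1.7
    speed_noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in TRACK_MODELS:
            raise ValueError(f"unknown model {self.model!r}; valid: {TRACK_MODELS}")
        if self.dt_h <= 0:
            raise ValueError("dt_h must be > 0")
        if self.duration_h < 2 * self.dt_h:
            raise ValueError("duration must cover at least two steps")
        if not 0 <= self.persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be > 0")
        if self.speed_noise_frac < 0:
            raise ValueError("speed_noise_frac must be >= 0")


def decaying_speed(t_h: np.ndarray | float, s0: float, s_inf: float, half_life_h: float):
    """Speed decaying from ``s0`` to plateau ``s_inf``: half-life form.

    ``S(t) = S_inf + (S0 − S_inf) · 2^(−t / half_life)``
    """
    return s_inf + (s0 - s_inf) * np.exp2(-np.asarray(t_h, dtype=float) / half_life_h)


def simulate_tracks(spec: TrajectorySpec) -> tuple[list[Track], GroundTruth]:
    """Simulate an ensemble of 2D tracks under the requested motion model.

    * ``random_walk``: i.i.d. Gaussian steps, per-axis variance 2·D·dt.
    * ``ballistic``: constant speed along a fixed (random) heading.
    * ``persistent``: constant step length; heading increments are
      wrapped-Gaussian with per-step direction correlation ``p``.
    * ``decaying_speed``: fresh random heading each step with step length
      S(t)·dt, S given by :func:`decaying_speed`.
    """
    rng = np.random.default_rng(spec.seed)
    n_steps = int(round(spec.duration_h / spec.dt_h))
    times = np.arange(n_steps + 1) * spec.dt_h
    tracks: list[Track] = []
    for k in range(spec.n_tracks):
        if spec.model == "random_walk":
            sd = np.sqrt(2 * spec.diffusion_um2_per_h * spec.dt_h)
            steps = rng.normal(0, sd, size=(n_steps, 2))
        elif spec.model == "ballistic":
            theta = rng.uniform(0, 2 * np.pi)
            step = spec.speed_um_per_h * spec.dt_h
            steps = np.tile(step * np.array([np.cos(theta), np.sin(theta)]), (n_steps, 1))
        elif spec.model == "persistent":
            # heading auto-correlation <cos(dtheta)> = p for wrapped-Gaussian
            # increments with sd sqrt(-2 ln p)
            sd = np.sqrt(-2 * np.log(spec.persistence)) if spec.persistence > 0 else np.pi
            theta = rng.uniform(0, 2 * np.pi) + np.concatenate(
                [[0.0], np.cumsum(rng.normal(0, sd, n_steps - 1))]
            )
            step = spec.speed_um_per_h * spec.dt_h
            steps = step * np.column_stack([np.cos(theta), np.sin(theta)])
        else:  # decaying_speed
            theta = rng.uniform(0, 2 * np.pi, n_steps)
            lengths = decaying_speed(
                times[:-1], spec.s0_um_per_h, spec.s_inf_um_per_h, spec.half_life_h
            ) * spec.dt_h
            if spec.speed_noise_frac > 0:
                lengths = lengths * np.clip(
                    rng.normal(1.0, spec.speed_noise_frac, n_steps), 0, None
                )
            steps = lengths[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(
            Track(track_id=f"t{k:03d}", times=times, xs=pos[:, 0], ys=pos[:, 1])
        )
    params = {
        "model": spec.model,
        "dt_h": spec.dt_h,
        "diffusion_um2_per_h": spec.diffusion_um2_per_h,
        "speed_um_per_h": spec.speed_um_per_h,
        "persistence": spec.persistence,
        "s0_um_per_h": spec.s0_um_per_h,
        "s_inf_um_per_h": spec.s_inf_um_per_h,
        "half_life_h": spec.half_life_h,
        "speed_noise_frac": spec.speed_noise_frac,
    }
    return tracks, GroundTruth(track_params=params)


# ---------------------------------------------------------------------------
# wound series
# ---------------------------------------------------------------------------


def make_wound_series(
    width_um: float = 400.0,
    closure_rate_um_per_h: float = 400.0 / 24.0,
    timepoints_h: Sequence[float] = (0.0, 6.0, 12.0, 18.0, 24.0),
    image_shape_px: tuple[int, int] = (300, 600),
    pixel_size_um: float = 1.0,
    cell_level: float = 100.0,
    texture_sd: float = 20.0,
    wound_sd: float = 1.0,
    seed: int = 0,
) -> tuple[list[np.ndarray], GroundTruth]:
    """Phase-contrast-like frames of a straight scratch wound closing linearly.

    The cell monolayer is a high-variance texture; the wound is a smooth
    band of width ``max(0, w0 − rate·t)`` centred horizontally.  True
    areas follow the closed form ``w(t) · image_height`` (µm²).
    """
    if width_um <= 0:
        raise ValueError("width_um must be > 0")
    if closure_rate_um_per_h < 0:
        raise ValueError("closure_rate_um_per_h must be >= 0")
    h, w = image_shape_px
    rng = np.random.default_rng(seed)
    frames: list[np.ndarray] = []
    true_areas: list[float] = []
    for t in timepoints_h:
        wt_um = max(0.0, width_um - closure_rate_um_per_h * t)
        n_cols = int(round(wt_um / pixel_size_um))
        frame = rng.normal(cell_level, texture_sd, size=(h, w))
        if n_cols > 0:
            x0 = (w - n_cols) // 2
            frame[:, x0 : x0 + n_cols] = rng.normal(
                cell_level, wound_sd, size=(h, n_cols)
            )
        frames.append(np.clip(frame, 0, None))
        true_areas.append(wt_um * h * pixel_size_um)
    return frames, GroundTruth(wound_areas_um2=true_areas)
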