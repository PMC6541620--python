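"""Config-driven orchestration of the full analysis.

A :class:`RunConfig` (YAML/JSON, schema-validated before any computation)
names the stages to execute — ``synth``, ``quantify``, ``motility``,
``wound``, ``report`` — together with every stage parameter and a master
seed.  Each random decision consumes a named sub-seed derived from the
master seed, recorded in the run's JSON sidecar, so a rerun of the same
config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .io_core import (
    ImageStack,
    Projection,
    RoiBox,
    Track,
    project,
    read_image_stack,
    read_tracks,
    write_image_stack,
    write_records,
    write_tracks,
)
from .motility import (
    average_speed,
    fit_msd_linear,
    classify_motion,
    fit_speed_decay,
    mean_speed_series,
    msd,
    running_average_speed,
)
from .quantification import (
    QuantRecord,
    aspect_ratio,
    centrosome_total_intensity,
    mean_intensity,
    nc_ratio,
    normalize_to_control,
)
from .segmentation import (
    SegmentationError,
    centrosome_mask,
    cortical_ring,
    segment_cell,
    segment_nucleus,
    select_random_boxes,
)
from .stats import compare_groups, summarize_groups
from .synthetic import (
    CellPhantomSpec,
    TrajectorySpec,
    make_cell_image,
    make_wound_series,
    simulate_tracks,
)
from .wound import residual_series, wound_area

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration schema
# ---------------------------------------------------------------------------


class SynthConfig(BaseModel):
    n_phantoms_per_level: int = Field(5, ge=1)
    enrichment_levels: list[float] = [1.0, 1.5, 2.0, 3.0]
    nc_ratio: float = Field(0.65, gt=0)
    noise_sd_frac: float = Field(0.05, ge=0)
    image_size_px: int = Field(192, ge=32)
    trajectory_models: list[str] = ["random_walk"]
    n_tracks: int = Field(40, ge=1)
    wound_width_um: float = Field(400.0, gt=0)
    wound_closure_rate_um_per_h: float = Field(400.0 / 24.0, ge=0)
    wound_timepoints_h: list[float] = [0.0, 6.0, 12.0, 18.0, 24.0]


class SegmentationConfig(BaseModel):
    offset_frac: float = 0.05
    window_px: int | None = None
    box_size_um: float = Field(3.88, gt=0)  # protrusion/random box edge
    nucleus_dilation_um: float = Field(2.0, ge=0)
    ring_thickness_um: float = Field(2.0, gt=0)
    ring_method: Literal["erosion", "edt"] = "erosion"


class MotilityConfig(BaseModel):
    window_h: float = Field(1.0, gt=0)
    max_lag_fraction: float = Field(0.25, gt=0, le=1)


class WoundConfig(BaseModel):
    window_px: int = Field(7, ge=3)
    std_threshold: float | None = 5.0
    min_area_px: int = Field(64, ge=1)


class ReportConfig(BaseModel):
    control_condition: str | None = None
    design: str = "kruskal-dunn"


class RunConfig(BaseModel):
    """Validated run configuration; see package docs for field meanings."""

    output_dir: str
    pixel_size_um: float = Field(..., gt=0)
    seed: int = 0
    stages: list[str] = ["synth", "quantify", "motility", "wound", "report"]
    image_manifest: list[dict] = []  # [{path, channel_map}] when not synthesising
    tracks_csv: str | None = None
    synth: SynthConfig = SynthConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    motility: MotilityConfig = MotilityConfig()
    wound: WoundConfig = WoundConfig()
    report: ReportConfig = ReportConfig()

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v: list[str]) -> list[str]:
        known = {"synth", "quantify", "motility", "wound", "report"}
        bad = set(v) - known
        if bad:
            raise ValueError(f"unknown stages {sorted(bad)}; valid: {sorted(known)}")
        return v


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML or JSON run configuration."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    return RunConfig.model_validate(raw)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _subseed(master: int, name: str) -> int:
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_synth(config: RunConfig, outdir: Path) -> dict:
    """Generate phantoms, trajectories and a wound series with truth files."""
    sc = config.synth
    phantom_dir = outdir / "phantoms"
    phantom_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for level in sc.enrichment_levels:
        for i in range(sc.n_phantoms_per_level):
            seed = _subseed(config.seed, f"phantom:{level}:{i}")
            spec = CellPhantomSpec(
                image_size_px=sc.image_size_px,
                pixel_size_um=config.pixel_size_um,
                cortical_enrichment_fold=level,
                nc_ratio=sc.nc_ratio,
                noise_sd_frac=sc.noise_sd_frac,
                seed=seed,
            )
            stack, truth = make_cell_image(spec)
            name = f"phantom_E{level:g}_{i:02d}"
            write_image_stack(stack, phantom_dir / f"{name}.tif")
            manifest.append(
                {
                    "name": name,
                    "path": str(phantom_dir / f"{name}.tif"),
                    "condition": f"E{level:g}",
                    "true_enrichment": level,
                    "true_nc_ratio": sc.nc_ratio,
                    "seed": seed,
                }
            )
    pd.DataFrame(manifest).to_csv(outdir / "phantom_manifest.csv", index=False)

    all_tracks = []
    truth_rows = []
    for model in sc.trajectory_models:
        seed = _subseed(config.seed, f"tracks:{model}")
        tracks, truth = simulate_tracks(
            TrajectorySpec(model=model, n_tracks=sc.n_tracks, seed=seed)
        )
        for tr in tracks:
            all_tracks.append(
                Track(
                    track_id=f"{model}:{tr.track_id}",
                    times=tr.times,
                    xs=tr.xs,
                    ys=tr.ys,
                )
            )
        truth_rows.append({"model": model, **truth.track_params, "seed": seed})
    write_tracks(all_tracks, outdir / "tracks.csv")
    pd.DataFrame(truth_rows).to_csv(outdir / "tracks_truth.csv", index=False)

    frames, wtruth = make_wound_series(
        width_um=sc.wound_width_um,
        closure_rate_um_per_h=sc.wound_closure_rate_um_per_h,
        timepoints_h=sc.wound_timepoints_h,
        pixel_size_um=1.0,
        seed=_subseed(config.seed, "wound"),
    )
    wound_dir = outdir / "wound_frames"
    wound_dir.mkdir(exist_ok=True)
    import tifffile

    for t, frame in zip(sc.wound_timepoints_h, frames):
        tifffile.imwrite(wound_dir / f"wound_t{t:g}.tif", frame.astype(np.float32))
    pd.DataFrame(
        {"time_h": sc.wound_timepoints_h, "true_area_um2": wtruth.wound_areas_um2}
    ).to_csv(outdir / "wound_truth.csv", index=False)
    return {"n_phantoms": len(manifest), "n_tracks": len(all_tracks)}


def quantify_stack(
    stack: ImageStack,
    cell_id: str,
    condition: str,
    batch: str,
    seg: SegmentationConfig,
    seed: int,
) -> list[QuantRecord]:
    """Segment one stack and measure the standard regional quantities."""
    actin = project(stack, "actin", "average")
    dapi = project(stack, "dapi", "average")
    pcnt = project(stack, "pcnt", "max")
    poi = project(stack, "poi", "max")

    cell = segment_cell(actin, window_px=seg.window_px, offset_frac=seg.offset_frac)
    nucleus = segment_nucleus(
        dapi, cell, window_px=seg.window_px, offset_frac=seg.offset_frac
    )
    ring = cortical_ring(
        cell,
        stack.pixel_size_um,
        thickness_um=seg.ring_thickness_um,
        method=seg.ring_method,
    )
    centro = centrosome_mask(pcnt)
    box_px = max(2, round(seg.box_size_um / stack.pixel_size_um))
    boxes = select_random_boxes(
        ring,
        nucleus,
        box_size_px=box_px,
        pixel_size_um=stack.pixel_size_um,
        dilation_um=seg.nucleus_dilation_um,
        seed=seed,
    )
    box_mask = np.zeros(cell.shape, dtype=bool)
    for b in boxes:
        box_mask |= b.to_mask(cell.shape)

    def rec(region: str, raw: float) -> QuantRecord:
        return QuantRecord(
            cell_id=cell_id,
            condition=condition,
            batch=batch,
            region=region,
            poi="poi",
            raw=raw,
        )

    records = [
        rec("cortex_random", mean_intensity(box_mask & ring, poi)),
        rec("whole_cell", mean_intensity(cell, poi)),
        rec("nucleus", mean_intensity(nucleus, poi)),
        rec("cytoplasm", mean_intensity(cell & ~nucleus, poi)),
        rec("centrosome", centrosome_total_intensity(centro, poi)),
    ]
    return records


def stage_quantify(config: RunConfig, outdir: Path) -> dict:
    """Segment + measure every image in the manifest (or the synth output)."""
    manifest_path = outdir / "phantom_manifest.csv"
    rows: list[dict]
    if config.image_manifest:
        rows = list(config.image_manifest)
    elif manifest_path.exists():
        rows = pd.read_csv(manifest_path).to_dict("records")
    else:
        raise FileNotFoundError(
            "no image manifest: configure image_manifest or run the synth stage"
        )
    records: list[QuantRecord] = []
    extra = []
    n_failed = 0
    for row in rows:
        stack = read_image_stack(
            row["path"],
            channel_map=row.get("channel_map", {"actin": 0, "dapi": 1, "pcnt": 2, "poi": 3}),
            pixel_size_um=config.pixel_size_um,
        )
        cell_id = str(row.get("name", Path(row["path"]).stem))
        try:
            recs = quantify_stack(
                stack,
                cell_id=cell_id,
                condition=str(row.get("condition", "unknown")),
                batch=str(row.get("batch", "batch0")),
                seg=config.segmentation,
                seed=_subseed(config.seed, f"boxes:{cell_id}"),
            )
        except SegmentationError as exc:
            n_failed += 1
            logger.warning("skipping %s: %s", cell_id, exc)
            continue
        records.extend(recs)
        actin = project(stack, "actin", "average")
        cell = segment_cell(
            actin,
            window_px=config.segmentation.window_px,
            offset_frac=config.segmentation.offset_frac,
        )
        extra.append({"cell_id": cell_id, "aspect_ratio": aspect_ratio(cell)})
    df = pd.DataFrame([r.__dict__ for r in records])
    write_records(df, outdir / "quant_records.csv")
    pd.DataFrame(extra).to_csv(outdir / "cell_shape.csv", index=False)
    return {"n_cells": len(rows) - n_failed, "n_failed": n_failed}


def stage_motility(config: RunConfig, outdir: Path) -> dict:
    tracks_path = Path(config.tracks_csv) if config.tracks_csv else outdir / "tracks.csv"
    if not tracks_path.exists():
        raise FileNotFoundError(f"no track table at {tracks_path}")
    tracks = read_tracks(tracks_path)
    by_model: dict[str, list[Track]] = {}
    for tr in tracks:
        model = tr.track_id.split(":")[0] if ":" in tr.track_id else "all"
        by_model.setdefault(model, []).append(tr)

    speed_rows, msd_rows, fit_payload = [], [], {}
    for model, group in sorted(by_model.items()):
        for tr in group:
            speed_rows.append(
                {
                    "model": model,
                    "track_id": tr.track_id,
                    "mean_speed_um_per_h": average_speed(tr),
                }
            )
        result = fit_msd_linear(msd(group, config.motility.max_lag_fraction))
        cls = classify_motion(result)
        for lag, val, npairs in zip(result.lags_h, result.msd_um2, result.n_pairs):
            msd_rows.append(
                {"model": model, "lag_h": lag, "msd_um2": val, "n_pairs": npairs}
            )
        fit_payload[model] = {
            "slope_um2_per_h": result.slope,
            "intercept_um2": result.intercept,
            "r_squared": result.r_squared,
            "diffusion_um2_per_h": result.slope / 4.0,
            "classification": cls.label,
            "alpha": cls.alpha,
            "n_tracks": len(group),
        }
        if model == "decaying_speed":
            mean_series = mean_speed_series(
                [running_average_speed(tr, config.motility.window_h) for tr in group]
            )
            fit = fit_speed_decay(mean_series)
            fit_payload[model]["half_life_h"] = fit.half_life_h
            fit_payload[model]["s0_um_per_h"] = fit.s0_um_per_h
            fit_payload[model]["s_inf_um_per_h"] = fit.s_inf_um_per_h
    pd.DataFrame(speed_rows).to_csv(outdir / "speeds.csv", index=False)
    pd.DataFrame(msd_rows).to_csv(outdir / "msd.csv", index=False)
    (outdir / "motility_fits.json").write_text(json.dumps(fit_payload, indent=2, sort_keys=True))
    return {"n_models": len(by_model)}


def stage_wound(config: RunConfig, outdir: Path) -> dict:
    import tifffile

    wound_dir = outdir / "wound_frames"
    if not wound_dir.exists():
        raise FileNotFoundError(f"no wound frames at {wound_dir}")
    frames = sorted(wound_dir.glob("wound_t*.tif"), key=lambda p: float(p.stem[7:]))
    times, areas = [], []
    for path in frames:
        t = float(path.stem[7:])
        frame = tifffile.imread(path)
        meas = wound_area(
            frame,
            pixel_size_um=1.0,
            window_px=config.wound.window_px,
            std_threshold=config.wound.std_threshold,
            min_area_px=config.wound.min_area_px,
        )
        times.append(t)
        areas.append(meas.area_um2)
    series = residual_series(areas, times)
    pd.DataFrame(
        {
            "time_h": series.timepoints_h,
            "area_um2": series.area_um2,
            "residual_pct": series.residual_pct,
            "recovered_pct": series.recovered_pct,
        }
    ).to_csv(outdir / "wound_series.csv", index=False)
    return {"n_frames": len(frames)}


def stage_report(config: RunConfig, outdir: Path) -> dict:
    records_path = outdir / "quant_records.csv"
    if not records_path.exists():
        raise FileNotFoundError(f"no quantification records at {records_path}")
    df = pd.read_csv(records_path)
    control = config.report.control_condition or sorted(df["condition"].unique())[0]
    df = normalize_to_control(df, control)
    write_records(df, outdir / "quant_records.csv")

    sub = df[df["region"] == "cortex_random"]
    groups = {c: g["normalized"].to_numpy() for c, g in sub.groupby("condition")}
    summaries = summarize_groups(groups)
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(
        outdir / "group_summary.csv", index=False
    )
    if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
        report = compare_groups(groups, control=control, design=config.report.design)
        report.table.to_csv(outdir / "group_comparisons.csv", index=False)
        omnibus = {"stat": report.omnibus_stat, "p": report.omnibus_p}
    else:
        omnibus = None
    return {"control": control, "omnibus": omnibus}


STAGES = {
    "synth": stage_synth,
    "quantify": stage_quantify,
    "motility": stage_motility,
    "wound": stage_wound,
    "report": stage_report,
}


def run(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run summary.

    Writes a JSON sidecar with the config, its hash, the derived
    sub-seeds consumed, and the package version.  Deterministic given
    the config (including its master seed).
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": _config_hash(config), "version": __version__}
    order = [s for s in ("synth", "quantify", "motility", "wound", "report") if s in config.stages]
    for stage in order:
        logger.info("running stage %s", stage)
        summary[stage] = STAGES[stage](config, outdir)
    (outdir / "run_metadata.json").write_text(
        json.dumps(
            {
                "config": config.model_dump(),
                "config_hash": summary["config_hash"],
                "package_version": __version__,
                "stages_run": order,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return summary
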