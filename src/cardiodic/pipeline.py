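"""Formats, configuration, manifests, and the end-to-end pipeline.

The pipeline chains simulate -> calibrate -> track -> correspond/lift ->
analyze -> report.  All tabular outputs are CSV with stable, versioned
headers (column order is part of the contract); cameras and manifests are
JSON; configuration is YAML with CLI flags taking precedence.  Logging goes
to stderr.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
import re
import time
from dataclasses import dataclass, field as dc_field

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import dic as dic_mod
from . import metrics as met
from . import stereo as st
from . import synthgen as sg
from .dic import DisplacementField, ImageSequence, SubsetGrid

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

FIELD_CSV_COLUMNS = ["frame", "point_id", "x_ref_px", "y_ref_px",
                     "u_px", "v_px", "u_mm", "v_mm", "w_mm", "zncc", "valid"]
GT_CSV_COLUMNS = ["frame", "point_id", "X_mm", "Y_mm", "Z_mm",
                  "ux_mm", "uy_mm", "uz_mm", "Exx", "Eyy", "Exy", "L_mm"]
TRACE_CSV_COLUMNS = ["time_s", "value", "std", "beat_index", "flag"]
CHARPOINT_CSV_COLUMNS = ["beat", "name", "value", "units", "frame"]


class PipelineError(Exception):
    pass


class FormatError(PipelineError):
    pass


class FrameGapError(PipelineError):
    pass


class StageError(PipelineError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class AcquisitionConfig:
    frame_rate: float = 17.0     # Hz
    mm_per_px: float = 0.1


@dataclass
class DicConfig:
    subset_size: int = dic_mod.DEFAULT_SUBSET_SIZE
    step: int = dic_mod.DEFAULT_STEP
    mode: str = "incremental"
    zncc_min: float = 0.2
    roi: tuple | None = None     # (x0, y0, w, h) px; None -> central half


@dataclass
class MetricsConfig:
    roi: tuple | None = None
    extensometer: tuple | None = None    # ((x1, y1), (x2, y2)) px
    smoothing_window: int = met.DEFAULT_SMOOTHING_WINDOW
    min_beat_s: float = met.DEFAULT_MIN_BEAT_S
    prominence_frac: float = met.DEFAULT_PROMINENCE_FRAC
    strain_reference: str = "start"      # "start" | "end_systole"
    strain_window: int = 5


@dataclass
class SimulateConfig:
    pattern: sg.SpecklePatternParams = dc_field(default_factory=sg.SpecklePatternParams)
    motion: sg.MotionModelParams = dc_field(default_factory=sg.MotionModelParams)
    image_size: tuple = (512, 512)
    stereo: bool = True
    n_frames: int | None = None
    bit_depth: int = 8
    calibration_noise_px: float = 0.1
    rig_distance_mm: float = 500.0
    rig_half_angle_deg: float = 12.0


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the per-module defaults."""

    paths: dict = dc_field(default_factory=dict)
    acquisition: AcquisitionConfig = dc_field(default_factory=AcquisitionConfig)
    dic: DicConfig = dc_field(default_factory=DicConfig)
    metrics: MetricsConfig = dc_field(default_factory=MetricsConfig)
    simulate: SimulateConfig | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return _asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        cfg = cls()
        if "paths" in d:
            cfg.paths = dict(d["paths"])
        if "seed" in d:
            cfg.seed = int(d["seed"])
        if "acquisition" in d:
            cfg.acquisition = AcquisitionConfig(**d["acquisition"])
        if "dic" in d:
            dd = dict(d["dic"])
            if dd.get("roi") is not None:
                dd["roi"] = tuple(dd["roi"])
            cfg.dic = DicConfig(**dd)
        if "metrics" in d:
            dm = dict(d["metrics"])
            if dm.get("roi") is not None:
                dm["roi"] = tuple(dm["roi"])
            if dm.get("extensometer") is not None:
                dm["extensometer"] = tuple(tuple(p) for p in dm["extensometer"])
            cfg.metrics = MetricsConfig(**dm)
        if d.get("simulate") is not None:
            ds = dict(d["simulate"])
            if "pattern" in ds:
                ds["pattern"] = sg.SpecklePatternParams(**ds["pattern"])
            if "motion" in ds:
                dmn = dict(ds["motion"])
                for key in ("anisotropy", "translation_amplitude", "center"):
                    if dmn.get(key) is not None:
                        dmn[key] = tuple(dmn[key])
                ds["motion"] = sg.MotionModelParams(**dmn)
            if "image_size" in ds:
                ds["image_size"] = tuple(ds["image_size"])
            cfg.simulate = SimulateConfig(**ds)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _asdict(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _asdict(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _asdict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Image IO
# ---------------------------------------------------------------------------


_LUMA = np.array([0.2125, 0.7154, 0.0721])


def _to_gray(frame: np.ndarray, source: str) -> np.ndarray:
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        logger.warning("read_image_sequence: converting RGB input %s to luminance", source)
        return (frame[..., :3].astype(float) @ _LUMA).astype(frame.dtype)
    raise FormatError(f"unsupported frame shape {frame.shape} in {source}")


def read_image_sequence(path_or_pattern: str, frame_rate: float) -> ImageSequence:
    """Load a multi-page TIFF or a zero-padded numbered frame set.

    Timestamps are synthesized from ``frame_rate``.  A missing index in a
    numbered set raises :class:`FrameGapError` naming the frame; frames of
    mixed dimensions raise :class:`FormatError`.
    """
    p = str(path_or_pattern)
    if os.path.isfile(p) and p.lower().endswith((".tif", ".tiff")):
        stack = tifffile.imread(p)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim == 3 and stack.shape[-1] in (3, 4) and stack.shape[0] not in (3, 4):
            stack = np.stack([_to_gray(f, p) for f in stack[None]]) if stack.ndim == 3 else stack
        frames = [_to_gray(f, p) if f.ndim == 3 else f for f in stack]
    else:
        files = sorted(glob.glob(p))
        if not files:
            raise FormatError(f"no frames match {p}")
        indices = []
        for f in files:
            m = re.findall(r"(\d+)", os.path.basename(f))
            if not m:
                raise FormatError(f"cannot parse a frame index from {f}")
            indices.append(int(m[-1]))
        order = np.argsort(indices)
        indices = [indices[i] for i in order]
        files = [files[i] for i in order]
        for prev, cur in zip(indices, indices[1:]):
            if cur != prev + 1:
                raise FrameGapError(f"missing frame {prev + 1} in sequence {p}")
        frames = [_to_gray(np.asarray(iio.imread(f)), f) for f in files]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"mixed frame dimensions {sorted(shapes)} in {p}")
    stack = np.stack(frames)
    bit_depth = 16 if stack.dtype.itemsize > 1 else 8
    return ImageSequence(frames=stack, frame_rate=frame_rate, bit_depth=bit_depth)


def write_image_sequence(seq: ImageSequence, path: str, metadata: dict | None = None):
    """Multi-page TIFF plus a JSON sidecar with acquisition metadata."""
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
    meta = {"frame_rate_hz": seq.frame_rate, "bit_depth": seq.bit_depth,
            "camera_id": seq.camera_id, "n_frames": int(seq.n_frames)}
    meta.update(metadata or {})
    with open(path + ".json", "w") as fh:
        json.dump(_asdict(meta), fh, indent=1)


# ---------------------------------------------------------------------------
# Tabular IO
# ---------------------------------------------------------------------------


def field_to_csv(field: DisplacementField, path: str):
    """Field export; pixel centres at integers, origin top-left, x right, y down."""
    nf, n = field.n_frames, field.n_points
    frame = np.repeat(np.arange(nf), n)
    pid = np.tile(np.arange(n), nf)
    x = np.tile(field.grid.centers[:, 0], nf)
    y = np.tile(field.grid.centers[:, 1], nf)
    if field.units == "px":
        u_px = field.u[:, :, 0].ravel()
        v_px = field.u[:, :, 1].ravel()
        if field.mm_per_px is not None:
            u_mm = u_px * field.mm_per_px
            v_mm = v_px * field.mm_per_px
        else:
            u_mm = np.full_like(u_px, np.nan)
            v_mm = np.full_like(v_px, np.nan)
        w_mm = np.full_like(u_px, np.nan)
    else:
        u_px = np.full(nf * n, np.nan)
        v_px = np.full(nf * n, np.nan)
        u_mm = field.u[:, :, 0].ravel()
        v_mm = field.u[:, :, 1].ravel()
        w_mm = (field.u[:, :, 2].ravel() if field.n_components == 3
                else np.full(nf * n, np.nan))
    df = pd.DataFrame({
        "frame": frame, "point_id": pid, "x_ref_px": x, "y_ref_px": y,
        "u_px": u_px, "v_px": v_px, "u_mm": u_mm, "v_mm": v_mm, "w_mm": w_mm,
        "zncc": field.zncc.ravel(), "valid": field.valid.ravel().astype(int),
    })
    df.to_csv(path, index=False, columns=FIELD_CSV_COLUMNS)
    meta = {
        "format_version": 1, "units": field.units,
        "subset_size": field.grid.subset_size, "step": field.grid.step,
        "mm_per_px": field.mm_per_px, "mode": field.accumulation_mode,
        "reference_frame": field.reference_frame,
        "timestamps_s": field.timestamps.tolist(),
        "grid_shape": list(field.grid.shape) if field.grid.shape else None,
        "roi": list(field.grid.roi) if field.grid.roi else None,
        "coordinate_convention": "pixel centres at integers, origin top-left, x right, y down",
    }
    with open(path + ".meta.json", "w") as fh:
        json.dump(_asdict(meta), fh, indent=1)


def field_from_csv(path: str) -> DisplacementField:
    df = pd.read_csv(path)
    with open(path + ".meta.json") as fh:
        meta = json.load(fh)
    nf = int(df["frame"].max()) + 1
    n = int(df["point_id"].max()) + 1
    first = df[df["frame"] == 0].sort_values("point_id")
    centers = first[["x_ref_px", "y_ref_px"]].to_numpy()
    grid = SubsetGrid(centers=centers, subset_size=meta["subset_size"],
                      step=meta["step"],
                      roi=tuple(meta["roi"]) if meta.get("roi") else None,
                      shape=tuple(meta["grid_shape"]) if meta.get("grid_shape") else None)
    df = df.sort_values(["frame", "point_id"])
    units = meta["units"]
    if units == "px":
        u = df[["u_px", "v_px"]].to_numpy().reshape(nf, n, 2)
    else:
        w = df["w_mm"].to_numpy()
        if np.isfinite(w).any():
            u = df[["u_mm", "v_mm", "w_mm"]].to_numpy().reshape(nf, n, 3)
        else:
            u = df[["u_mm", "v_mm"]].to_numpy().reshape(nf, n, 2)
    return DisplacementField(
        grid=grid, u=u,
        valid=df["valid"].to_numpy().reshape(nf, n).astype(bool),
        zncc=df["zncc"].to_numpy().reshape(nf, n),
        timestamps=np.asarray(meta["timestamps_s"], dtype=float),
        units=units, mm_per_px=meta.get("mm_per_px"),
        reference_frame=meta.get("reference_frame", 0),
        accumulation_mode=meta.get("mode", "incremental"),
    )


def ground_truth_to_csv(gt: sg.GroundTruthRecord, path: str):
    nf, n = gt.displacements.shape[:2]
    rows = {
        "frame": np.repeat(np.arange(nf), n),
        "point_id": np.tile(np.arange(n), nf),
        "X_mm": np.tile(gt.points_mm[:, 0], nf),
        "Y_mm": np.tile(gt.points_mm[:, 1], nf),
        "Z_mm": np.tile(gt.points_mm[:, 2], nf),
        "ux_mm": gt.displacements[:, :, 0].ravel(),
        "uy_mm": gt.displacements[:, :, 1].ravel(),
        "uz_mm": gt.displacements[:, :, 2].ravel(),
        "Exx": np.repeat(gt.strain[:, 0], n),
        "Eyy": np.repeat(gt.strain[:, 1], n),
        "Exy": np.repeat(gt.strain[:, 2], n),
        "L_mm": (np.repeat(gt.extensometer_length, n)
                 if gt.extensometer_length is not None else np.full(nf * n, np.nan)),
    }
    pd.DataFrame(rows).to_csv(path, index=False, columns=GT_CSV_COLUMNS)


def trace_to_csv(trace: met.Trace, path: str, beats: met.BeatSegmentation | None = None):
    beat_idx = np.full(len(trace), -1)
    if beats is not None:
        for bi, (s, e) in enumerate(beats.intervals):
            beat_idx[s:e] = bi
    flags = np.where(np.isfinite(trace.values), "ok", "missing")
    pd.DataFrame({
        "time_s": trace.timestamps, "value": trace.values,
        "std": trace.dispersion, "beat_index": beat_idx, "flag": flags,
    }).to_csv(path, index=False, columns=TRACE_CSV_COLUMNS)


def trace_from_csv(path: str, label: str = "", units: str = "") -> met.Trace:
    df = pd.read_csv(path)
    return met.Trace(df["value"].to_numpy(), df["time_s"].to_numpy(),
                     df["std"].to_numpy(), label=label, units=units)


def charpoints_to_csv(cp: met.CharacteristicPoints, path: str):
    rows = []
    named = [("TV_s", cp.tv_s, "cm/s"), ("TV_e", cp.tv_e, "cm/s"),
             ("TV_a", cp.tv_a, "cm/s"), ("SR_s", cp.sr_s, "1/s"),
             ("SR_e", cp.sr_e, "1/s"), ("SR_a", cp.sr_a, "1/s")]
    for name, entries, units in named:
        for beat, pt in enumerate(entries):
            if pt is not None:
                rows.append({"beat": beat, "name": name, "value": pt.value,
                             "units": units, "frame": pt.frame})
    for beat, val in enumerate(cp.s_s):
        if val is not None:
            rows.append({"beat": beat, "name": "S_s", "value": val,
                         "units": "%", "frame": -1})
    pd.DataFrame(rows, columns=CHARPOINT_CSV_COLUMNS).to_csv(path, index=False)


def camera_to_json(cam: st.CameraModel, path: str):
    with open(path, "w") as fh:
        json.dump({
            "projection_row_major": cam.projection.ravel().tolist(),
            "image_size": list(cam.image_size) if cam.image_size else None,
            "convention": "3x4 homogeneous matrix, world mm -> image px; "
                          "rows stored row-major; pixel centres at integers, "
                          "origin top-left, x right, y down",
        }, fh, indent=1)


def camera_from_json(path: str) -> st.CameraModel:
    with open(path) as fh:
        d = json.load(fh)
    return st.CameraModel(
        projection=np.asarray(d["projection_row_major"], dtype=float).reshape(3, 4),
        image_size=tuple(d["image_size"]) if d.get("image_size") else None,
    )


def calibration_table_to_csv(table: pd.DataFrame, path: str):
    table.to_csv(path, index=False)


def calibration_table_from_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Manifest and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    seed: int = 0
    timings_s: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)
    outputs: dict = dc_field(default_factory=dict)

    def write(self, path: str):
        with open(path, "w") as fh:
            json.dump(_asdict(dataclasses.asdict(self)), fh, indent=1)


def _tracking_grid(cfg: PipelineConfig, image_shape) -> SubsetGrid:
    h, w = image_shape
    roi = cfg.dic.roi or (w // 4, h // 4, w // 2, h // 2)
    return SubsetGrid.from_roi(roi, image_shape,
                               subset_size=cfg.dic.subset_size, step=cfg.dic.step)


def run_pipeline(config: PipelineConfig, out_dir: str) -> RunManifest:
    """Execute the full chain and write every artifact under ``out_dir``.

    Stages: simulate (optional) -> calibrate (stereo only) -> track per
    camera -> correspond + lift (stereo) -> analyze -> report.  Any stage
    failure raises :class:`StageError` naming the stage, after writing a
    partial manifest.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    stage = "setup"
    t_start = time.time()

    def tick(name):
        nonlocal stage, t_start
        manifest.timings_s[stage] = round(time.time() - t_start, 3)
        stage, t_start = name, time.time()

    try:
        cams = None
        gt = None
        sequences = []
        if config.simulate is not None:
            stage = "simulate"
            sim = config.simulate
            grid = _tracking_grid(config, (sim.image_size[1], sim.image_size[0]))
            ext = (np.asarray(config.metrics.extensometer, dtype=float)
                   if config.metrics.extensometer else None)
            if sim.stereo:
                cam1, cam2 = st.make_stereo_rig(
                    distance_mm=sim.rig_distance_mm,
                    half_angle_deg=sim.rig_half_angle_deg,
                    mm_per_px=config.acquisition.mm_per_px,
                    image_size=sim.image_size)
                n_frames = sim.n_frames or sg._default_n_frames(
                    sim.motion, config.acquisition.frame_rate)
                seq1, seq2, gt = sg.generate_stereo_sequences(
                    sim.pattern, sim.motion, (cam1, cam2), n_frames,
                    config.acquisition.frame_rate,
                    mm_per_px=config.acquisition.mm_per_px,
                    bit_depth=sim.bit_depth, grid=grid, extensometer_px=ext)
                sequences = [seq1, seq2]
                target = sg.default_calibration_target(
                    center=(0.0, 0.0, 0.0), extent_mm=(40.0, 40.0, 25.0),
                    seed=config.seed)
                table = sg.render_calibration_views(
                    target, (cam1, cam2),
                    pixel_noise_sigma=sim.calibration_noise_px, seed=config.seed)
                calibration_table_to_csv(table, os.path.join(out_dir, "calibration.csv"))
                cams = (cam1, cam2)
            else:
                seq, gt = sg.generate_sequence(
                    sim.pattern, sim.motion, image_size=sim.image_size,
                    mm_per_px=config.acquisition.mm_per_px,
                    frame_rate=config.acquisition.frame_rate,
                    n_frames=sim.n_frames, bit_depth=sim.bit_depth,
                    grid=grid, extensometer_px=ext)
                sequences = [seq]
            for i, s in enumerate(sequences):
                write_image_sequence(s, os.path.join(out_dir, f"cam{i + 1}.tif"),
                                     {"mm_per_px": config.acquisition.mm_per_px})
            ground_truth_to_csv(gt, os.path.join(out_dir, "ground_truth.csv"))
            manifest.outputs["ground_truth"] = "ground_truth.csv"
        else:
            stage = "load"
            for key in ("images_cam1", "images_cam2"):
                if key in config.paths:
                    sequences.append(read_image_sequence(
                        config.paths[key], config.acquisition.frame_rate))
            if not sequences:
                raise FormatError("config.paths must provide images_cam1 (and optionally images_cam2)")

        stereo_run = len(sequences) == 2
        tick("calibrate")
        calibrated = None
        if stereo_run:
            table_path = (os.path.join(out_dir, "calibration.csv")
                          if config.simulate is not None else config.paths.get("calibration"))
            if table_path and os.path.exists(table_path):
                table = calibration_table_from_csv(table_path)
                world = table[["X_mm", "Y_mm", "Z_mm"]].to_numpy()
                res1 = st.calibrate_dlt(world, table[["cam1_x_px", "cam1_y_px"]].to_numpy(),
                                        image_size=tuple(sequences[0].shape[::-1]))
                res2 = st.calibrate_dlt(world, table[["cam2_x_px", "cam2_y_px"]].to_numpy(),
                                        image_size=tuple(sequences[1].shape[::-1]))
                calibrated = (res1, res2)
                camera_to_json(res1.camera, os.path.join(out_dir, "camera1.json"))
                camera_to_json(res2.camera, os.path.join(out_dir, "camera2.json"))
                manifest.outputs["calibration_rms_px"] = [res1.rms_error, res2.rms_error]
            elif cams is None:
                raise FormatError("stereo run without a calibration table")

        tick("track")
        grid = _tracking_grid(config, sequences[0].shape)
        fields = []
        disparity = None
        disp_valid = None
        if stereo_run:
            use_cams = tuple(r.camera for r in calibrated) if calibrated else cams
            disparity, _dq, disp_valid = st.stereo_correspond(
                sequences[0].frames[0], sequences[1].frames[0], grid,
                search_radius=60)
            # camera-2 grid starts at the matched positions
            grid2 = SubsetGrid(centers=grid.centers + disparity,
                               subset_size=grid.subset_size, step=grid.step,
                               roi=grid.roi, shape=grid.shape)
            f1 = dic_mod.accumulate_sequence(sequences[0], grid, mode=config.dic.mode,
                                             mm_per_px=config.acquisition.mm_per_px)
            f2 = dic_mod.accumulate_sequence(sequences[1], grid2, mode=config.dic.mode,
                                             mm_per_px=config.acquisition.mm_per_px)
            f1 = dic_mod.quality_filter(f1, config.dic.zncc_min)
            f2 = dic_mod.quality_filter(f2, config.dic.zncc_min)
            fields = [f1, f2]
            field = st.lift_fields_to_3d(f1, f2, disparity, use_cams[0], use_cams[1],
                                         disparity_valid=disp_valid)
        else:
            f1 = dic_mod.accumulate_sequence(sequences[0], grid, mode=config.dic.mode,
                                             mm_per_px=config.acquisition.mm_per_px)
            field = dic_mod.quality_filter(f1, config.dic.zncc_min)
            fields = [field]
            manifest.warnings.append("single-camera run: out-of-plane (u_z) unavailable")
        for i, f in enumerate(fields):
            field_to_csv(f, os.path.join(out_dir, f"field_cam{i + 1}.csv"))
        field_to_csv(field, os.path.join(out_dir, "field.csv"))

        tick("analyze")
        results = analyze_field(field, config.metrics)
        for name, trace in results["traces"].items():
            trace_to_csv(trace, os.path.join(out_dir, f"trace_{name}.csv"),
                         beats=results.get("beats"))
        if results.get("charpoints") is not None:
            charpoints_to_csv(results["charpoints"], os.path.join(out_dir, "characteristic_points.csv"))
        manifest.outputs["n_beats"] = (results["beats"].n_beats
                                       if results.get("beats") else 0)

        tick("report")
        report(results, out_dir)
        tick("done")
    except Exception as exc:
        manifest.warnings.append(f"stage {stage} failed: {exc}")
        manifest.write(os.path.join(out_dir, "manifest.json"))
        raise StageError(stage, exc) from exc

    manifest.write(os.path.join(out_dir, "manifest.json"))
    return manifest


def analyze_field(field: DisplacementField, mcfg: MetricsConfig) -> dict:
    """Displacement field -> all trace families and characteristic points."""
    if mcfg.roi is not None:
        roi = met.ROIDef(*mcfg.roi)
    else:
        c = field.grid.centers
        roi = met.ROIDef(c[:, 0].min(), c[:, 1].min(),
                         c[:, 0].max() - c[:, 0].min(), c[:, 1].max() - c[:, 1].min())
    traces = roi_tr = met.roi_traces(field, roi)
    out: dict = {"traces": dict(roi_tr), "roi": roi}

    beats = None
    try:
        beats = met.segment_beats(roi_tr["V_l"], mcfg.min_beat_s, mcfg.prominence_frac)
    except met.SegmentationError as exc:
        logger.warning("beat segmentation failed: %s", exc)
    out["beats"] = beats

    tv = met.tissue_velocity(roi_tr["V_l"], mcfg.smoothing_window)
    out["traces"]["TV"] = tv

    cp = met.CharacteristicPoints()
    if beats is not None:
        cp = met.detect_tv_points(tv, beats)

    summary = met.local_strain_field(field, window_points=mcfg.strain_window)
    out["strain_summary"] = summary
    out["traces"]["e_max"] = met.Trace(summary.e_max_mean, field.timestamps,
                                       summary.e_max_std, label="e_max", units="%")
    out["traces"]["e_min"] = met.Trace(summary.e_min_mean, field.timestamps,
                                       summary.e_min_std, label="e_min", units="%")

    if mcfg.extensometer is not None:
        ext = met.ExtensometerDef(tuple(mcfg.extensometer[0]), tuple(mcfg.extensometer[1]))
        length = met.extensometer_length(field, ext)
        out["traces"]["L"] = length
        if beats is not None:
            fs = met.fractional_shortening(length, beats)
            out["traces"]["FS"] = fs
            strain, rate, cp_sr = met.strain_and_rate(length, beats, mcfg.smoothing_window)
            out["traces"]["strain"] = strain
            out["traces"]["strain_rate"] = rate
            cp.sr_s, cp.sr_e, cp.sr_a, cp.s_s = cp_sr.sr_s, cp_sr.sr_e, cp_sr.sr_a, cp_sr.s_s
        lon, hor = met.directional_strains(field, ext)
        out["traces"]["longitudinal_strain"] = lon
        out["traces"]["horizontal_strain"] = hor
    out["charpoints"] = cp
    return out


def report(results: dict, out_dir: str):
    """Write PNG figures for every trace family plus a plain-text index."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = {
        "vector_components": ["V_x", "V_y", "V_z", "V_l"],
        "principal_strains": ["e_max", "e_min"],
        "tissue_velocity": ["TV"],
        "fractional_shortening": ["FS"],
        "strain": ["strain", "longitudinal_strain", "horizontal_strain"],
        "strain_rate": ["strain_rate"],
    }
    written = []
    traces = results["traces"]
    for fname, labels in groups.items():
        present = [lab for lab in labels if lab in traces]
        if not present:
            continue
        fig, ax = plt.subplots(figsize=(8, 4))
        for lab in present:
            tr = traces[lab]
            ax.errorbar(tr.timestamps, tr.values, yerr=tr.dispersion,
                        label=f"{lab} [{tr.units}]", elinewidth=0.5, capsize=1)
        ax.set_xlabel("time [s]")
        ax.legend(loc="best", fontsize=8)
        ax.grid(alpha=0.3)
        path = os.path.join(out_dir, f"report_{fname}.png")
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(os.path.basename(path))
    with open(os.path.join(out_dir, "report_index.txt"), "w") as fh:
        fh.write("generated figures:\n")
        for w in written:
            fh.write(f"  {w}\n")
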