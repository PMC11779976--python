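"""File I/O: multi-page TIFF for movies and stacks (with JSON sidecars for
pixel/voxel sizes and rates), CSV for traces and tables, JSON for stimulus
schedules and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from nvp.core import (
    AnatomyStack,
    CalciumTraces,
    DiameterTrace,
    HemoRecording,
    Kymograph,
    LocomotionTrace,
    StimulusSchedule,
    VelocityTrace,
    VesselMovie,
)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: VesselMovie, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, movie.data.astype(np.float32))
    with open(_sidecar(path), "w") as fh:
        json.dump({"pixel_size_um": movie.pixel_size,
                   "frame_rate_hz": movie.frame_rate}, fh)


def read_movie(path, pixel_size: float | None = None,
               frame_rate: float | None = None) -> VesselMovie:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        pixel_size = pixel_size or meta.get("pixel_size_um")
        frame_rate = frame_rate or meta.get("frame_rate_hz")
    if pixel_size is None or frame_rate is None:
        raise ValueError("pixel_size and frame_rate required (sidecar "
                         "missing)")
    return VesselMovie(data=data, pixel_size=pixel_size, frame_rate=frame_rate)


def write_kymograph(kymo: Kymograph, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, kymo.data.astype(np.float32))
    with open(_sidecar(path), "w") as fh:
        json.dump({"pixel_size_um": kymo.pixel_size,
                   "line_rate_hz": kymo.line_rate}, fh)


def read_kymograph(path, pixel_size: float | None = None,
                   line_rate: float | None = None) -> Kymograph:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        data = pd.read_csv(path, header=None).to_numpy(dtype=float)
    else:
        data = tifffile.imread(path).astype(float)
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
        pixel_size = pixel_size or meta.get("pixel_size_um")
        line_rate = line_rate or meta.get("line_rate_hz")
    if pixel_size is None or line_rate is None:
        raise ValueError("pixel_size and line_rate required")
    return Kymograph(data=data, line_rate=line_rate, pixel_size=pixel_size)


def write_stack(stack: AnatomyStack, path) -> None:
    path = Path(path)
    tifffile.imwrite(path, stack.data.astype(np.float32))
    with open(_sidecar(path), "w") as fh:
        json.dump({"voxel_size_um": list(stack.voxel_size)}, fh)


def read_stack(path, voxel_size=None) -> AnatomyStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    sc = _sidecar(path)
    if sc.exists() and voxel_size is None:
        voxel_size = json.loads(sc.read_text())["voxel_size_um"]
    if voxel_size is None:
        raise ValueError("voxel_size required (sidecar missing)")
    return AnatomyStack(data=data, voxel_size=tuple(voxel_size))


def write_diameter_trace(trace: DiameterTrace, path) -> None:
    pd.DataFrame({
        "time_s": trace.times,
        "value": trace.values,
        "valid": trace.valid,
        "reason": [r or "" for r in (trace.reasons or [""] * len(trace.values))],
    }).to_csv(path, index=False)


def read_trace_csv(path, value_col: str | None = None,
                   rate: float | None = None) -> tuple[np.ndarray, float]:
    """Generic trace reader: returns (values, sample_rate inferred from the
    time column unless given)."""
    df = pd.read_csv(path)
    if value_col is None:
        value_col = [c for c in df.columns if c != "time_s"][0]
    values = df[value_col].to_numpy(dtype=float)
    if rate is None:
        t = df["time_s"].to_numpy(dtype=float)
        rate = 1.0 / np.median(np.diff(t))
    return values, float(rate)


def write_velocity_trace(trace: VelocityTrace, path) -> None:
    pd.DataFrame({
        "time_s": trace.window_centers,
        "value": trace.values,
        "valid": trace.valid,
        "quality": trace.quality,
    }).to_csv(path, index=False)


def read_hemo_csv(path, sample_rate: float = 40.0) -> HemoRecording:
    df = pd.read_csv(path)
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        sample_rate = 1.0 / np.median(np.diff(t))
        df = df.drop(columns=["time_s"])
    return HemoRecording(channels=df, sample_rate=sample_rate)


def read_locomotion_csv(path, sample_rate: float | None = None) -> LocomotionTrace:
    df = pd.read_csv(path)
    if sample_rate is None:
        t = df["time_s"].to_numpy(dtype=float)
        sample_rate = 1.0 / np.median(np.diff(t))
    return LocomotionTrace(speed=df["speed"].to_numpy(dtype=float),
                           sample_rate=sample_rate)


def read_calcium_csv(path, sample_rate: float | None = None) -> CalciumTraces:
    df = pd.read_csv(path)
    if "time_s" in df.columns:
        if sample_rate is None:
            t = df["time_s"].to_numpy(dtype=float)
            sample_rate = 1.0 / np.median(np.diff(t))
        df = df.drop(columns=["time_s"])
    return CalciumTraces(dff=df.to_numpy(dtype=float).T, sample_rate=sample_rate,
                         cell_ids=list(df.columns))


def read_schedule_json(path) -> StimulusSchedule:
    return StimulusSchedule.from_dict(json.loads(Path(path).read_text()))
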