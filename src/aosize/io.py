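"""Readers and writers for scenes, calibration and results.

Echograms travel as HDF5 (datasets ``values_db``, ``ping_times_s``,
``sample_ranges_m``) with a CSV fallback; frames as numbered PNGs with a
``frame_index, t_seconds`` manifest; truth, traces and results as CSV;
calibration as YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .echogram import Echogram, Trace
from .fusion import BeamProjectionModel, CameraIntrinsics, SizingResult
from .synthetic import GroundTruthFish, SyntheticScene

__all__ = [
    "write_echogram_h5", "read_echogram_h5",
    "write_echogram_csv", "read_echogram_csv",
    "write_frames", "read_frame_manifest",
    "write_truth_csv", "read_truth_csv",
    "write_calibration_yaml", "read_calibration_yaml",
    "write_traces_csv", "write_results_csv",
    "write_run_manifest", "config_hash", "save_scene",
]


def write_echogram_h5(eg: Echogram, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values_db", data=eg.values_db)
        f.create_dataset("ping_times_s", data=eg.ping_times_s)
        f.create_dataset("sample_ranges_m", data=eg.sample_ranges_m)


def read_echogram_h5(path: str | Path) -> Echogram:
    with h5py.File(path, "r") as f:
        return Echogram(
            values_db=f["values_db"][...],
            ping_times_s=f["ping_times_s"][...],
            sample_ranges_m=f["sample_ranges_m"][...],
        )


def write_echogram_csv(eg: Echogram, path: str | Path) -> None:
    """CSV fallback: matrix with ping times as the index and ranges as columns."""
    df = pd.DataFrame(eg.values_db, index=eg.ping_times_s,
                      columns=eg.sample_ranges_m)
    df.to_csv(path, index_label="ping_time_s")


def read_echogram_csv(path: str | Path) -> Echogram:
    df = pd.read_csv(path, index_col=0)
    return Echogram(
        values_db=df.to_numpy(dtype=float),
        ping_times_s=df.index.to_numpy(dtype=float),
        sample_ranges_m=np.array([float(c) for c in df.columns]),
    )


def write_frames(frames, out_dir: str | Path) -> Path:
    """Write numbered PNGs plus a timestamp manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (t, img) in enumerate(frames):
        name = f"frame_{i:06d}.png"
        iio.imwrite(out / name, img)
        rows.append({"frame_index": i, "t_seconds": t, "filename": name})
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_frame_manifest(manifest_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(manifest_path)


def write_truth_csv(truth: list[GroundTruthFish], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(f) for f in truth])
    df.to_csv(path, index=False, float_format="%.17g")


def read_truth_csv(path: str | Path) -> list[GroundTruthFish]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [GroundTruthFish(**row) for row in df.to_dict(orient="records")]


def write_calibration_yaml(intr: CameraIntrinsics, bpm: BeamProjectionModel,
                           path: str | Path) -> None:
    doc = {
        "intrinsics": {
            "f_px": float(intr.f_px),
            "cx": float(intr.cx),
            "cy": float(intr.cy),
            "distortion": [float(k) for k in intr.distortion],
        },
        "beam": {
            "half_angle_deg": float(bpm.half_angle_deg),
            "narrowing_factor": float(bpm.narrowing_factor),
            "axis_ranges_m": [float(r) for r in bpm.axis_ranges_m],
            "axis_points_px": [[float(x), float(y)]
                               for x, y in bpm.axis_points_px],
        },
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_calibration_yaml(path: str | Path):
    doc = yaml.safe_load(Path(path).read_text())
    intr = CameraIntrinsics(
        f_px=doc["intrinsics"]["f_px"],
        cx=doc["intrinsics"]["cx"],
        cy=doc["intrinsics"]["cy"],
        distortion=np.array(doc["intrinsics"].get("distortion", [0.0, 0.0])),
    )
    bpm = BeamProjectionModel(
        half_angle_deg=doc["beam"]["half_angle_deg"],
        narrowing_factor=doc["beam"].get("narrowing_factor", 1.0),
        axis_ranges_m=np.array(doc["beam"]["axis_ranges_m"]),
        axis_points_px=np.array(doc["beam"]["axis_points_px"]),
    )
    return intr, bpm


def write_traces_csv(traces: list[Trace], path: str | Path) -> None:
    rows = []
    for t in traces:
        rows.append({
            "trace_id": t.trace_id,
            "t_center_s": t.t_center_s,
            "area_cells": t.area_cells,
            "solidity": t.solidity,
            "max_ts_db": t.max_ts_db,
            "min_ts_db": t.min_ts_db,
            "mean_range_m": t.mean_range_m,
            "n_pings": t.n_pings,
            "sti_m_per_ping": t.sti,
            "sti_m_per_s": t.sti_per_s,
            "sti_intercept_m": t.sti_intercept_m,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_fits_csv(fits, path: str | Path) -> None:
    """Per-frame model-fit table (one row per fit)."""
    rows = []
    for f in fits:
        p = f.params
        rows.append({
            "frame_index": f.frame_index,
            "t_s": f.t_s,
            "fei": f.fei,
            "accepted": f.accepted,
            "sx": p.sx, "sy": p.sy, "l": p.l,
            "alpha_deg": p.alpha_deg, "theta_b_deg": p.theta_b_deg,
            "w0": p.w[0], "lp": p.lp, "sp": p.sp,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_tracks_csv(tracks, path: str | Path) -> None:
    """One row per track with summary statistics of its fits."""
    rows = []
    for t in tracks:
        frames = [f.frame_index for f in t.fits]
        rows.append({
            "track_id": t.track_id,
            "n_fits": len(t.fits),
            "first_frame": min(frames),
            "last_frame": max(frames),
            "mean_length_px": float(np.mean(t.lengths_px)),
            "mean_heading_deg": float(np.mean(t.directions_deg)),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_results_csv(results: list[SizingResult], path: str | Path) -> None:
    rows = [{
        "track_id": r.track_id,
        "trace_id": r.trace_id,
        "n_measurements": r.n_measurements,
        "ml_m": r.ml_m,
        "sfl_m": r.sfl_m,
        "width_m": r.width_m,
        "tilt_class": r.tilt_class,
    } for r in results]
    pd.DataFrame(rows).to_csv(path, index=False)


def config_hash(obj) -> str:
    """Stable hash of any JSON-serializable (or dataclass) configuration."""

    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(type(o))

    blob = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_run_manifest(path: str | Path, *, seed: int, config,
                       counts: dict) -> None:
    doc = {"seed": seed, "config_hash": config_hash(config), "counts": counts}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))


def save_scene(scene: SyntheticScene, out_dir: str | Path,
               echogram_format: str = "h5") -> Path:
    """Write a full scene (echogram, frames, truth, calibration) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if echogram_format == "h5":
        write_echogram_h5(scene.echogram, out / "echogram.h5")
    else:
        write_echogram_csv(scene.echogram, out / "echogram.csv")
    write_frames(scene.frames, out / "frames")
    write_truth_csv(scene.truth, out / "truth.csv")
    write_calibration_yaml(scene.intrinsics, scene.beam, out / "calibration.yaml")
    return out
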