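"""Reading and writing the pipeline's file formats.

Trajectories travel as CSV (t, x_mm, y_mm, detected) preceded by a JSON
header comment carrying calibration, threshold and frame rate; frame
stacks as multi-page TIFF or directories of numbered PNGs; walker ground
truth as CSV plus a JSON sidecar of the generative parameters.
"""
from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth, WalkerParams
from .tracking import Calibration, Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "write_frames",
    "read_frames",
    "write_ground_truth",
    "read_ground_truth",
    "trajectory_from_ground_truth",
]

_HEADER_PREFIX = "# "


def write_trajectory(traj: Trajectory, path, threshold: Optional[float] = None) -> None:
    meta = {"frame_rate": traj.frame_rate, "arena_radius_mm": traj.arena_radius_mm}
    if threshold is not None:
        meta["threshold"] = threshold
    if traj.calibration is not None:
        meta["calibration"] = dataclasses.asdict(traj.calibration)
    df = pd.DataFrame({"t": traj.t, "x_mm": traj.x, "y_mm": traj.y,
                       "detected": traj.detected.astype(int)})
    with open(path, "w") as fh:
        fh.write(_HEADER_PREFIX + json.dumps(meta, sort_keys=True) + "\n")
        df.to_csv(fh, index=False)


def read_trajectory(path) -> Trajectory:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_HEADER_PREFIX):
            raise ValueError(f"{path}: missing JSON header line")
        meta = json.loads(first[len(_HEADER_PREFIX):])
        df = pd.read_csv(fh)
    cal = None
    if "calibration" in meta:
        c = meta["calibration"]
        cal = Calibration(mm_per_pixel=c["mm_per_pixel"],
                          arena_center=tuple(c["arena_center"]),
                          arena_radius_px=c["arena_radius_px"])
    return Trajectory(t=df["t"].to_numpy(), x=df["x_mm"].to_numpy(),
                      y=df["y_mm"].to_numpy(),
                      detected=df["detected"].to_numpy().astype(bool),
                      frame_rate=meta["frame_rate"], calibration=cal,
                      arena_radius_mm=meta.get("arena_radius_mm", 10.0))


def write_frames(frames: np.ndarray, path) -> None:
    """Write a frame stack as multi-page TIFF (.tif) or numbered PNGs (dir)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, np.asarray(frames))
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", np.asarray(frame))


def read_frames(path) -> np.ndarray:
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".bmp", ".tif", ".tiff"))
        if not files:
            raise ValueError(f"no image files in {path}")
        return np.stack([iio.imread(p) for p in files])
    return tifffile.imread(path)


def write_ground_truth(truth: GroundTruth, csv_path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"t": truth.t, "x_mm": truth.x, "y_mm": truth.y,
                  "state": np.where(truth.states == 1, "run", "rest")}
                 ).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(dataclasses.asdict(truth.params), fh, indent=2, sort_keys=True)


def read_ground_truth(csv_path) -> GroundTruth:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    with open(csv_path.with_suffix(".json")) as fh:
        params = WalkerParams(**json.load(fh))
    return GroundTruth(t=df["t"].to_numpy(), x=df["x_mm"].to_numpy(),
                       y=df["y_mm"].to_numpy(),
                       states=(df["state"] == "run").to_numpy().astype(np.uint8),
                       params=params)


def trajectory_from_ground_truth(truth: GroundTruth) -> Trajectory:
    """Treat simulated positions as a perfectly tracked trajectory."""
    return Trajectory(t=truth.t, x=truth.x, y=truth.y,
                      detected=np.ones(len(truth), dtype=bool),
                      frame_rate=truth.params.frame_rate,
                      arena_radius_mm=truth.params.arena_radius)
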