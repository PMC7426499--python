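"""Spontaneous locomotor activity (SLA) metrics.

The trajectory is divided into 1-second quanta and the mean speed of
movement in each quantum is computed; quanta below 1 mm/s are classified
as rest, the rest as run.  Five per-fly parameters are then derived:

1. index of activity — fraction of quanta classified run;
2. run frequency — run bouts per 100 s of valid record;
3. running speed — mean quantum speed over run quanta, mm/s;
4. total speed — mean quantum speed over all valid quanta, mm/s;
5. run bout time — mean duration of maximal blocks of consecutive run
   quanta, s;

plus a centrophobia index (fraction of detected samples in the outer wall
annulus), quantifying the wall-following tendency.

Quantum speed convention: each displacement between successive detected
samples is attributed to the quantum containing its earlier sample, and
the quantum speed is the attributed path length divided by the quantum
duration.  This partitions the whole path exactly across quanta (at f
frames per second a full quantum carries f steps), so a fly moving
steadily at v mm/s scores v mm/s.  Quanta with fewer than two detected
samples are flagged invalid and excluded from every parameter; invalid
quanta also break run bouts.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .tracking import Trajectory

__all__ = [
    "AnalysisConfig",
    "QuantizedTrack",
    "Bout",
    "SLAProfile",
    "quantize",
    "segment_bouts",
    "compute_profile",
    "plot_track",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Quantization and classification settings.

    ``quantum`` is the analysis bin (s), ``rest_threshold`` the mean-speed
    cutoff (mm/s) below which a quantum counts as rest (speeds >= threshold
    are run — only "lower than" is rest), and ``centro_annulus_fraction``
    the radius fraction beyond which a sample counts as wall-zone for the
    centrophobia index.
    """

    quantum: float = 1.0
    rest_threshold: float = 1.0
    record_duration: Optional[float] = None
    centro_annulus_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.quantum <= 0:
            raise ValueError("quantum must be positive")
        if self.rest_threshold <= 0:
            raise ValueError("rest_threshold must be positive")
        if not 0.0 < self.centro_annulus_fraction < 1.0:
            raise ValueError("centro_annulus_fraction must lie in (0, 1)")


@dataclass
class QuantizedTrack:
    """Per-quantum mean speeds, rest/run states and validity flags."""

    mean_speed: np.ndarray  # mm/s per quantum
    is_run: np.ndarray  # bool; False for rest and for invalid quanta
    valid: np.ndarray  # bool; quantum had >= 2 detected samples
    n_detected: np.ndarray  # detected samples per quantum
    mean_radius: np.ndarray  # mm, NaN where no detected samples
    quantum: float
    rest_threshold: float
    n_detected_total: int
    n_outer_total: int  # detected samples beyond the centrophobia annulus
    arena_radius_mm: float

    def __len__(self) -> int:
        return self.mean_speed.size

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))


@dataclass(frozen=True)
class Bout:
    """Maximal block of consecutive run quanta."""

    start_quantum: int
    length_quanta: int
    quantum: float = 1.0

    @property
    def duration(self) -> float:
        return self.length_quanta * self.quantum


@dataclass
class SLAProfile:
    """The five SLA parameters plus centrophobia for one fly.

    ``index_of_activity`` is reported as a fraction in [0, 1]
    (``index_of_activity_percent`` gives the percentage scale);
    ``running_speed`` and ``run_bout_time`` are ``None`` when the record
    contains no run quantum / no bout.
    """

    index_of_activity: float
    run_frequency: float  # bouts per 100 s
    running_speed: Optional[float]  # mm/s
    total_speed: float  # mm/s
    run_bout_time: Optional[float]  # s
    centrophobia_index: Optional[float]
    n_quanta: int
    fly_id: Optional[str] = None

    @property
    def index_of_activity_percent(self) -> float:
        return 100.0 * self.index_of_activity

    def as_dict(self) -> dict:
        return {
            "fly_id": self.fly_id,
            "index_of_activity": self.index_of_activity,
            "run_frequency": self.run_frequency,
            "running_speed": self.running_speed,
            "total_speed": self.total_speed,
            "run_bout_time": self.run_bout_time,
            "centrophobia_index": self.centrophobia_index,
            "n_quanta": self.n_quanta,
        }


def quantize(traj: Trajectory, cfg: AnalysisConfig = AnalysisConfig()) -> QuantizedTrack:
    """Divide a trajectory into quanta and classify each as rest or run."""
    n_samples = len(traj)
    span = n_samples / traj.frame_rate
    duration = cfg.record_duration if cfg.record_duration is not None else span
    n_quanta = int(math.floor(min(duration, span) / cfg.quantum + 1e-9))
    if n_quanta < 1:
        raise ValueError("trajectory shorter than one quantum")

    qidx = np.floor(traj.t / cfg.quantum + 1e-9).astype(np.int64)
    in_span = qidx < n_quanta
    det = traj.detected & in_span
    didx = np.flatnonzero(traj.detected)  # steps may start in-span, end beyond

    path = np.zeros(n_quanta)
    if didx.size >= 2:
        a, b = didx[:-1], didx[1:]
        steps = np.hypot(traj.x[b] - traj.x[a], traj.y[b] - traj.y[a])
        qa = qidx[a]
        keep = qa < n_quanta
        np.add.at(path, qa[keep], steps[keep])

    n_det = np.zeros(n_quanta, dtype=np.int64)
    np.add.at(n_det, qidx[det], 1)
    radius = np.hypot(traj.x, traj.y)
    rsum = np.zeros(n_quanta)
    np.add.at(rsum, qidx[det], radius[det])
    with np.errstate(invalid="ignore"):
        mean_radius = np.where(n_det > 0, rsum / np.maximum(n_det, 1), np.nan)

    valid = n_det >= 2
    mean_speed = path / cfg.quantum
    mean_speed[~valid] = np.nan
    is_run = valid & (np.nan_to_num(mean_speed, nan=0.0) >= cfg.rest_threshold)

    arena_r = traj.arena_radius_mm
    outer = det & (radius > cfg.centro_annulus_fraction * arena_r)
    return QuantizedTrack(
        mean_speed=mean_speed,
        is_run=is_run,
        valid=valid,
        n_detected=n_det,
        mean_radius=mean_radius,
        quantum=cfg.quantum,
        rest_threshold=cfg.rest_threshold,
        n_detected_total=int(det.sum()),
        n_outer_total=int(outer.sum()),
        arena_radius_mm=arena_r,
    )


def segment_bouts(qt: QuantizedTrack) -> List[Bout]:
    """Maximal consecutive blocks of run quanta (edge bouts included)."""
    if len(qt) == 0:
        raise ValueError("empty quantized track")
    padded = np.concatenate(([False], qt.is_run, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return [Bout(start_quantum=int(s), length_quanta=int(e - s), quantum=qt.quantum)
            for s, e in zip(starts, stops)]


def compute_profile(qt: QuantizedTrack, bouts: Optional[Sequence[Bout]] = None,
                    cfg: AnalysisConfig = AnalysisConfig(),
                    fly_id: Optional[str] = None) -> SLAProfile:
    """Compute the five SLA parameters (and centrophobia) from a quantized track.

    By construction ``run_frequency * run_bout_time = 100 * index_of_activity``
    exactly whenever bouts exist.
    """
    if bouts is None:
        bouts = segment_bouts(qt)
    n_valid = qt.n_valid
    if n_valid == 0:
        raise ValueError("no valid quanta in record")
    n_run = int(np.sum(qt.is_run))
    index_of_activity = n_run / n_valid
    valid_time = n_valid * qt.quantum
    run_frequency = 100.0 * len(bouts) / valid_time
    running_speed = float(np.mean(qt.mean_speed[qt.is_run])) if n_run else None
    total_speed = float(np.mean(qt.mean_speed[qt.valid]))
    run_bout_time = (sum(b.duration for b in bouts) / len(bouts)) if bouts else None
    centro = (qt.n_outer_total / qt.n_detected_total) if qt.n_detected_total else None
    return SLAProfile(
        index_of_activity=index_of_activity,
        run_frequency=run_frequency,
        running_speed=running_speed,
        total_speed=total_speed,
        run_bout_time=run_bout_time,
        centrophobia_index=centro,
        n_quanta=n_valid,
        fly_id=fly_id,
    )


def plot_track(traj: Trajectory, path=None, ax=None, show_arena: bool = True):
    """Visualize the full trajectory inside the arena circle (axes in mm)."""
    import matplotlib
    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    det = traj.detected
    ax.plot(traj.x[det], traj.y[det], lw=0.5, color="tab:blue")
    if show_arena:
        r = traj.arena_radius_mm
        circle = plt.Circle((0, 0), r, fill=False, color="black", lw=1.0)
        ax.add_patch(circle)
        ax.set_xlim(-1.05 * r, 1.05 * r)
        ax.set_ylim(-1.05 * r, 1.05 * r)
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
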