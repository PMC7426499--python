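import numpy as np
import pytest

from flysla import (AnalysisConfig, BrainPhantomParams, QuantizedTrack,
                    Trajectory, WalkerParams)


@pytest.fixture
def short_walker_params():
    return WalkerParams(duration=20.0, seed=11)


@pytest.fixture
def brain_phantom_params():
    return BrainPhantomParams()


def make_quantized(states, speeds, quantum=1.0, rest_threshold=1.0,
                   n_outer=0, n_detected_total=None):
    """Build a QuantizedTrack directly from run/rest letters and speeds.

    ``states`` is a string of R (run) / S (rest) / X (invalid); ``speeds``
    per-quantum mean speeds (ignored for X).
    """
    states = list(states)
    n = len(states)
    speeds = np.asarray(speeds, dtype=float)
    valid = np.array([s != "X" for s in states])
    is_run = np.array([s == "R" for s in states])
    assert not np.any(is_run & ~valid)
    mean_speed = np.where(valid, speeds, np.nan)
    n_det = np.where(valid, 10, 0)
    if n_detected_total is None:
        n_detected_total = int(n_det.sum())
    return QuantizedTrack(
        mean_speed=mean_speed, is_run=is_run, valid=valid, n_detected=n_det,
        mean_radius=np.full(n, 5.0), quantum=quantum, rest_threshold=rest_threshold,
        n_detected_total=n_detected_total, n_outer_total=n_outer,
        arena_radius_mm=10.0)


def straight_line_trajectory(step_mm, n_samples, frame_rate=10.0):
    """A fly moving in a straight line by ``step_mm`` each frame."""
    i = np.arange(n_samples)
    return Trajectory(t=i / frame_rate, x=-5.0 + step_mm * i, y=np.zeros(n_samples),
                      detected=np.ones(n_samples, dtype=bool), frame_rate=frame_rate,
                      arena_radius_mm=10.0)
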