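"""Threshold-and-centroid fly tracking.

The fly position in each frame is the intensity-weighted mean position of
all pixels strictly brighter than a fixed threshold (default 60 on the
8-bit scale); frames with no super-threshold pixel are flagged missing, not
interpolated.  Pixel coordinates are converted to arena-centered millimetre
coordinates using a :class:`Calibration` fitted from the bright arena disk
(the standard chamber is 20 mm across) or supplied manually.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from skimage import measure

DEFAULT_THRESHOLD = 60.0
STANDARD_ARENA_DIAMETER_MM = 20.0

__all__ = [
    "Calibration",
    "Trajectory",
    "detect_centroid",
    "track_frames",
    "calibrate_from_arena",
    "DEFAULT_THRESHOLD",
    "STANDARD_ARENA_DIAMETER_MM",
]


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre mapping of the arena.

    ``arena_center`` is (col, row) in pixel coordinates (pixel centers at
    integer coordinates, 0-based).  For the standard chamber,
    ``2 * arena_radius_px * mm_per_pixel`` equals 20 mm.
    """

    mm_per_pixel: float
    arena_center: tuple  # (cx, cy) pixels
    arena_radius_px: float

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise ValueError("mm_per_pixel must be positive")
        if self.arena_radius_px <= 0:
            raise ValueError("arena_radius_px must be positive")

    @property
    def arena_radius_mm(self) -> float:
        return self.arena_radius_px * self.mm_per_pixel

    def px_to_mm(self, cx, cy):
        """Arena-centered mm coordinates; image y-axis negated so up is +y."""
        x = (np.asarray(cx, dtype=float) - self.arena_center[0]) * self.mm_per_pixel
        y = -(np.asarray(cy, dtype=float) - self.arena_center[1]) * self.mm_per_pixel
        return x, y

    def mm_to_px(self, x, y):
        cx = np.asarray(x, dtype=float) / self.mm_per_pixel + self.arena_center[0]
        cy = -np.asarray(y, dtype=float) / self.mm_per_pixel + self.arena_center[1]
        return cx, cy


@dataclass
class Trajectory:
    """Time-stamped fly positions in arena-centered mm with missing flags."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    detected: np.ndarray  # bool per sample
    frame_rate: float
    calibration: Optional[Calibration] = None
    arena_radius_mm: float = 10.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n = self.t.size
        if not (self.x.size == self.y.size == self.detected.size == n):
            raise ValueError("t, x, y and detected must have equal length")
        if self.calibration is not None:
            self.arena_radius_mm = self.calibration.arena_radius_mm

    def __len__(self) -> int:
        return self.t.size

    @property
    def fraction_detected(self) -> float:
        return float(np.mean(self.detected)) if len(self) else 0.0

    @property
    def radius(self) -> np.ndarray:
        """Distance from arena center, mm (NaN-free only for detected samples)."""
        return np.hypot(self.x, self.y)


def detect_centroid(frame: np.ndarray, threshold: float = DEFAULT_THRESHOLD,
                    weighting: str = "intensity"):
    """Centroid of super-threshold pixels, or ``None`` if none exceed it.

    Returns ``(cx, cy)`` — column, row — as the mean position of all pixels
    with intensity strictly above ``threshold``, weighted by intensity
    (``weighting="intensity"``, sub-pixel accurate) or unweighted over the
    binary mask (``weighting="binary"``).
    """
    frame = np.asarray(frame)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    rows, cols = np.nonzero(frame > threshold)
    if rows.size == 0:
        return None
    if weighting == "intensity":
        w = frame[rows, cols].astype(float)
        total = w.sum()
        return float((cols * w).sum() / total), float((rows * w).sum() / total)
    if weighting == "binary":
        return float(cols.mean()), float(rows.mean())
    raise ValueError(f"unknown weighting {weighting!r}")


def track_frames(frames: Iterable[np.ndarray], calibration: Calibration,
                 threshold: float = DEFAULT_THRESHOLD, frame_rate: float = 10.0,
                 weighting: str = "intensity") -> Trajectory:
    """Track a frame sequence into an arena-centered mm trajectory.

    Missing detections are carried as flagged gaps (position NaN), never
    interpolated.
    """
    cxs, cys, det = [], [], []
    n = 0
    for frame in frames:
        n += 1
        c = detect_centroid(frame, threshold, weighting=weighting)
        if c is None:
            cxs.append(np.nan)
            cys.append(np.nan)
            det.append(False)
        else:
            cxs.append(c[0])
            cys.append(c[1])
            det.append(True)
    if n == 0:
        raise ValueError("no frames to track")
    x, y = calibration.px_to_mm(np.array(cxs), np.array(cys))
    t = np.arange(n) / frame_rate
    return Trajectory(t=t, x=x, y=y, detected=np.array(det), frame_rate=frame_rate,
                      calibration=calibration)


def calibrate_from_arena(frame_or_mask: np.ndarray,
                         diameter_mm: float = STANDARD_ARENA_DIAMETER_MM,
                         threshold: Optional[float] = None) -> Calibration:
    """Fit the arena circle from the largest bright connected region.

    The illuminated chamber disk is segmented (Otsu threshold by default,
    or a boolean mask passed directly), and the disk diameter is taken as
    the mean of the region's row and column extents measured between
    extreme pixel centers — exact for a clean rasterized disk.
    ``mm_per_pixel = diameter_mm / diameter_px``.
    """
    img = np.asarray(frame_or_mask)
    if img.ndim != 2:
        raise ValueError("expected a 2-D frame or mask")
    if img.dtype == bool:
        mask = img
    else:
        if threshold is None:
            from skimage.filters import threshold_otsu
            threshold = threshold_otsu(img)
        mask = img > threshold
    if not mask.any():
        raise ValueError("no arena detected: no bright region in frame")
    labels = measure.label(mask)
    props = measure.regionprops(labels)
    region = max(props, key=lambda p: p.area)
    minr, minc, maxr, maxc = region.bbox  # max bounds are exclusive
    height = maxr - 1 - minr
    width = maxc - 1 - minc
    diameter_px = (height + width) / 2.0
    if diameter_px < 20:
        raise ValueError(
            f"fitted arena diameter {diameter_px:.0f} px is too small; resolution too low")
    center = ((minc + maxc - 1) / 2.0, (minr + maxr - 1) / 2.0)
    return Calibration(mm_per_pixel=diameter_mm / diameter_px,
                       arena_center=center,
                       arena_radius_px=diameter_px / 2.0)
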