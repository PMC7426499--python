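"""Dot-blot densitometry: spot optical density, normalization, calibration.

Optical density (OD) of a membrane spot is operationalized as the mean
intensity of a local background annulus minus the mean intensity of the
spot disk, floored at zero — on a light membrane a darker spot gives a
larger OD, and subtracting a local annulus makes the measure invariant to
global illumination offsets.  Three normalization schemes are supported:
ratio to a β-actin reference spot, ratio to a total-protein reference, and
division by the mean OD of an age cohort (conventional units, cohort mean
exactly 1).  A serial-dilution standard series is fitted by ordinary least
squares (OD = slope * concentration + intercept) and can be inverted to
estimate concentrations; the antibody-specificity check is the OD drop
after pre-blocking the antibody with its antigen.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

__all__ = [
    "SpotSpec",
    "SpotOD",
    "NormalizedSignal",
    "StandardCurveFit",
    "measure_od",
    "normalize_to_reference",
    "normalize_to_cohort_mean",
    "fit_standard_curve",
    "invert_standard_curve",
    "specificity_delta",
]


@dataclass(frozen=True)
class SpotSpec:
    """A circular spot ROI with a disjoint local background annulus."""

    center: Tuple[float, float]  # (row, col) pixels
    radius: float
    annulus: Tuple[float, float] = None  # (inner, outer) radii; default (r+2, r+6)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("spot radius must be positive")
        ann = self.annulus if self.annulus is not None else (self.radius + 2, self.radius + 6)
        object.__setattr__(self, "annulus", (float(ann[0]), float(ann[1])))
        if not self.radius < self.annulus[0] < self.annulus[1]:
            raise ValueError("annulus must be disjoint from the spot disk "
                             "(radius < inner < outer)")


@dataclass(frozen=True)
class SpotOD:
    """Background-minus-spot optical density of one spot."""

    od: float
    spot_mean: float
    background_mean: float
    n_pixels: int


@dataclass(frozen=True)
class NormalizedSignal:
    value: float
    scheme: str  # beta_actin | total_protein | age_mean_cu


@dataclass(frozen=True)
class StandardCurveFit:
    """OLS line through a serial-dilution series: od = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    concentration_range: Tuple[float, float]


def _masks(image: np.ndarray, spec: SpotSpec):
    h, w = image.shape
    r, c = spec.center
    outer = spec.annulus[1]
    if not (r - outer >= 0 and r + outer < h and c - outer >= 0 and c + outer < w):
        raise ValueError("spot and annulus must lie inside the image")
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - r) ** 2 + (xx - c) ** 2
    disk = d2 <= spec.radius ** 2
    ann = (d2 >= spec.annulus[0] ** 2) & (d2 <= spec.annulus[1] ** 2)
    return disk, ann


def measure_od(image: np.ndarray, spec: SpotSpec) -> SpotOD:
    """Spot OD = max(0, annulus mean - spot-disk mean intensity)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale membrane image")
    disk, ann = _masks(image, spec)
    if not ann.any():
        raise ValueError("empty background annulus")
    spot_mean = float(image[disk].mean())
    bg_mean = float(image[ann].mean())
    return SpotOD(od=max(0.0, bg_mean - spot_mean), spot_mean=spot_mean,
                  background_mean=bg_mean, n_pixels=int(disk.sum()))


def normalize_to_reference(target: SpotOD, reference: SpotOD,
                           scheme: str = "beta_actin") -> NormalizedSignal:
    """Ratio normalization to a loading-control spot (β-actin or total protein)."""
    if scheme not in ("beta_actin", "total_protein"):
        raise ValueError(f"unknown ratio scheme {scheme!r}")
    if reference.od <= 0:
        raise ValueError("reference OD is zero; ratio undefined")
    return NormalizedSignal(value=target.od / reference.od, scheme=scheme)


def normalize_to_cohort_mean(ods: Sequence[float]) -> list:
    """Divide each OD by the cohort mean (conventional units; mean becomes 1)."""
    arr = np.asarray([getattr(o, "od", o) for o in ods], dtype=float)
    if arr.size == 0:
        raise ValueError("empty cohort")
    m = arr.mean()
    if m <= 0:
        raise ValueError("cohort mean OD is zero; normalization undefined")
    return [NormalizedSignal(value=float(v / m), scheme="age_mean_cu") for v in arr]


def fit_standard_curve(concentrations: Sequence[float],
                       ods: Sequence[float]) -> StandardCurveFit:
    """OLS fit of OD against concentration for a dilution series."""
    conc = np.asarray(concentrations, dtype=float)
    od = np.asarray([getattr(o, "od", o) for o in ods], dtype=float)
    if conc.size != od.size:
        raise ValueError("concentrations and ODs must have equal length")
    if conc.size < 3:
        raise ValueError("need at least 3 calibration points")
    if np.unique(conc).size < 2:
        raise ValueError("need at least 2 distinct concentrations")
    res = stats.linregress(conc, od)
    ss_res = float(np.sum((od - (res.slope * conc + res.intercept)) ** 2))
    ss_tot = float(np.sum((od - od.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurveFit(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2,
                            concentration_range=(float(conc.min()), float(conc.max())))


def invert_standard_curve(fit: StandardCurveFit, od: float) -> float:
    """Concentration estimate from an OD via the fitted line.

    Warns when the estimate falls outside the calibrated concentration range.
    """
    if fit.slope == 0:
        raise ValueError("cannot invert a flat standard curve")
    conc = (od - fit.intercept) / fit.slope
    lo, hi = fit.concentration_range
    if not lo <= conc <= hi:
        warnings.warn(f"inverted concentration {conc:.4g} lies outside the "
                      f"calibrated range [{lo:.4g}, {hi:.4g}]", stacklevel=2)
    return float(conc)


def specificity_delta(od_without_block: float, od_with_block: float) -> float:
    """OD drop after pre-blocking the antibody; positive means specific signal."""
    a = getattr(od_without_block, "od", od_without_block)
    b = getattr(od_with_block, "od", od_with_block)
    if a < 0 or b < 0:
        raise ValueError("ODs must be non-negative")
    delta = float(a - b)
    if delta < 0:
        warnings.warn("blocked OD exceeds unblocked OD (negative specificity delta)",
                      stacklevel=2)
    return delta
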