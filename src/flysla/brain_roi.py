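"""Pedunculus ROI ratiometry on confocal stacks.

In frontal scans of the fly brain the protein-bound 3-HOK signal dips in a
small region where the mushroom-body pedunculus (Ped) begins.  The dip is
quantified by the ratio statistic R = x/y, where x is the mean intensity of
a square ROI placed on the Ped and y the mean of an equal-size ROI
immediately above it (toward the image top), each averaged over the three
optical slices in which the Ped is most dimmed (lowest ROI mean).
Averaging over slices happens before the ratio is formed; a
ratio-per-slice-then-average variant is available behind a flag.  Because
R is a ratio of means from the same stack it is invariant to any global
intensity gain.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["ROISpec", "PedRatioResult", "select_dimmed_slices", "ped_ratio", "batch_ratios"]


@dataclass(frozen=True)
class ROISpec:
    """Square Ped ROI; the reference ROI is derived one side-length above.

    ``top_left`` is (row, col) of the Ped ROI's top-left pixel; the
    reference ROI has the same size and is shifted by ``offset`` pixels
    toward the image top (default: exactly one side length, so the two
    squares are adjacent and non-overlapping).
    """

    top_left: Tuple[int, int]
    side: int
    channel: int = 0
    offset: Optional[int] = None  # upward shift of the reference ROI; default = side

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("ROI side must be positive")
        off = self.side if self.offset is None else self.offset
        object.__setattr__(self, "offset", int(off))
        if self.offset < self.side:
            raise ValueError("offset smaller than side would overlap the ROIs")

    def rois(self, shape: Tuple[int, int]):
        """(x_roi, y_roi) as (row_slice, col_slice); validates both inside."""
        r, c = self.top_left
        s = self.side
        h, w = shape
        ry = r - self.offset
        if not (0 <= ry and r + s <= h and 0 <= c and c + s <= w):
            raise ValueError("ROI (or the derived reference ROI above it) "
                             "falls outside the image")
        return (slice(r, r + s), slice(c, c + s)), (slice(ry, ry + s), slice(c, c + s))


@dataclass(frozen=True)
class PedRatioResult:
    """Ped ROI mean x, above-ROI mean y, their ratio R, and slices used."""

    x: float
    y: float
    R: float
    slices_used: Tuple[int, ...]


def _channel_stack(stack: np.ndarray, channel: int) -> np.ndarray:
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 4:  # (slices, channels, H, W)
        stack = stack[:, channel]
    if stack.ndim != 3:
        raise ValueError("expected a (slices, height, width) or "
                         "(slices, channels, height, width) stack")
    return stack


def select_dimmed_slices(stack: np.ndarray, spec: ROISpec, k: int = 3) -> Tuple[int, ...]:
    """Indices of the k slices with lowest mean intensity in the Ped ROI.

    Ties are broken toward the lower slice index (stable sort).
    """
    vol = _channel_stack(stack, spec.channel)
    if vol.shape[0] < k:
        raise ValueError(f"stack has {vol.shape[0]} slices; need at least {k}")
    (xs, ys_cols), _ = spec.rois(vol.shape[1:])
    roi_means = vol[:, xs, ys_cols].mean(axis=(1, 2))
    order = np.argsort(roi_means, kind="stable")
    return tuple(sorted(int(i) for i in order[:k]))


def ped_ratio(stack: np.ndarray, spec: ROISpec, k: int = 3,
              slices: Optional[Sequence[int]] = None,
              per_slice_ratio: bool = False) -> PedRatioResult:
    """Compute R = x/y over the k most-dimmed slices.

    ``slices`` overrides automatic slice selection.  With
    ``per_slice_ratio=True`` the per-slice ratios are averaged instead of
    averaging x and y first (non-default variant).
    """
    vol = _channel_stack(stack, spec.channel)
    if slices is None:
        slices = select_dimmed_slices(vol, spec, k=k)
    slices = tuple(int(s) for s in slices)
    (xr, xc), (yr, yc) = spec.rois(vol.shape[1:])
    x_means = vol[list(slices), xr, xc].mean(axis=(1, 2))
    y_means = vol[list(slices), yr, yc].mean(axis=(1, 2))
    x = float(x_means.mean())
    y = float(y_means.mean())
    if per_slice_ratio:
        if np.any(y_means == 0):
            raise ValueError("reference ROI mean is zero in a selected slice")
        r = float(np.mean(x_means / y_means))
    else:
        if y == 0:
            raise ValueError("reference ROI mean is zero; ratio undefined")
        r = x / y
    return PedRatioResult(x=x, y=y, R=r, slices_used=slices)


def batch_ratios(stacks: Sequence[np.ndarray], specs, labels: Sequence[str],
                 brain_ids: Optional[Sequence[str]] = None, k: int = 3,
                 test: str = "t") -> Tuple[pd.DataFrame, Optional[dict]]:
    """Per-brain R table plus a two-group comparison of R.

    ``specs`` may be one :class:`ROISpec` shared by all stacks or one per
    stack.  The default group test is Welch's two-sided t-test (matching
    how per-brain R values are conventionally compared); ``test="mannwhitney"``
    uses the two-tailed Mann-Whitney U test instead.  With fewer than two
    groups, or any single-brain group, only the table is returned.
    """
    n = len(stacks)
    if isinstance(specs, ROISpec):
        specs = [specs] * n
    if not (len(specs) == len(labels) == n):
        raise ValueError("stacks, specs and labels must have equal length")
    if brain_ids is None:
        brain_ids = [f"brain_{i}" for i in range(n)]
    rows = []
    for bid, stack, spec, lab in zip(brain_ids, stacks, specs, labels):
        res = ped_ratio(stack, spec, k=k)
        rows.append({"brain_id": bid, "group": lab, "x": res.x, "y": res.y,
                     "R": res.R, "slices_used": ",".join(map(str, res.slices_used))})
    table = pd.DataFrame(rows)
    groups = table["group"].unique()
    result = None
    if len(groups) == 2:
        a = table.loc[table["group"] == groups[0], "R"].to_numpy()
        b = table.loc[table["group"] == groups[1], "R"].to_numpy()
        if a.size > 1 and b.size > 1:
            from .group_stats import mann_whitney_u, significance_tier
            if test == "t":
                from scipy.stats import ttest_ind
                t_res = ttest_ind(a, b, equal_var=False)
                p = float(t_res.pvalue)
                result = {"test": "welch_t", "statistic": float(t_res.statistic),
                          "p": p, "tier": significance_tier(p)}
            elif test == "mannwhitney":
                mw = mann_whitney_u(a, b)
                result = {"test": "mann_whitney", "statistic": mw.U,
                          "p": mw.p_two_tailed, "tier": mw.tier}
            else:
                raise ValueError(f"unknown test {test!r}")
    return table, result
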