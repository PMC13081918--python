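"""Regions of interest and ROI time-series extraction.

ROIs are geometric patches (discs or axis-aligned rectangles) in the same
coordinate frame as the field they are applied to: metres for simulated
chamber fields, micrometres for images.  The default chamber layout puts
six discs around the organoid — Top, Bottom, Left, Right at the rim,
Center at the organoid centre and Middle in the mid-chamber fluid —
mirroring the device's six readout regions.  The experimental layout is
three vertically stacked discs (ROI1 top, ROI2 middle, ROI3 bottom).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError
from .geometry import ChamberGeometry
from .transport import ConcentrationHistory

__all__ = [
    "Disc",
    "Rect",
    "ROISet",
    "default_chamber_rois",
    "experimental_rois",
    "ROITimeSeries",
    "extract_roi_timeseries",
]


@dataclass(frozen=True)
class Disc:
    cx: float
    cy: float
    r: float

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xx, yy = np.meshgrid(x, y, indexing="ij")
        return (xx - self.cx) ** 2 + (yy - self.cy) ** 2 <= self.r**2

    def bounds(self) -> tuple[float, float, float, float]:
        return self.cx - self.r, self.cx + self.r, self.cy - self.r, self.cy + self.r


@dataclass(frozen=True)
class Rect:
    x0: float
    x1: float
    y0: float
    y1: float

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xx, yy = np.meshgrid(x, y, indexing="ij")
        return (xx >= self.x0) & (xx <= self.x1) & (yy >= self.y0) & (yy <= self.y1)

    def bounds(self) -> tuple[float, float, float, float]:
        return self.x0, self.x1, self.y0, self.y1


class ROISet(dict):
    """Mapping of unique ROI names to patches (:class:`Disc`/:class:`Rect`)."""

    def __init__(self, patches: dict):
        super().__init__(patches)

    def validate_inside(self, width: float, height: float) -> None:
        for name, patch in self.items():
            x0, x1, y0, y1 = patch.bounds()
            if x0 < 0 or y0 < 0 or x1 > width or y1 > height:
                raise GeometryError(f"ROI {name!r} extends outside the domain")


_ROI_DIAMETER = 0.45e-3  # m, readout disc diameter in the chamber frame
_SQRT_HALF = 0.7071067811865476


def default_chamber_rois(geometry: ChamberGeometry,
                         diameter: float = _ROI_DIAMETER) -> ROISet:
    """Six-region chamber layout (Top/Bottom/Left/Right/Middle/Center).

    Top and Bottom sit just outside the organoid's upper and lower rim.
    Right is the upper-right (downstream, outlet-facing) rim surface and
    Left the lower-left (sheltered, wall-facing) rim surface — the
    surfaces whose exposure roles the device reads out.  Center is
    the organoid centre; Middle is the mid-chamber fluid midway between
    the organoid and the outlet-side wall.
    """
    cx, cy = geometry.organoid_center
    R = geometry.organoid_radius
    r = diameter / 2.0
    gap = 0.05e-3  # clearance between rim and readout disc
    d = R + r + gap
    c45 = d * _SQRT_HALF
    return ROISet({
        "Top": Disc(cx, cy + d, r),
        "Bottom": Disc(cx, cy - d, r),
        "Left": Disc(cx - c45, cy - c45, r),
        "Right": Disc(cx + c45, cy + c45, r),
        "Center": Disc(cx, cy, r),
        "Middle": Disc((cx + R + geometry.well_diameter) / 2.0,
                       0.6 * geometry.well_depth, r),
    })


def experimental_rois(width: float, height: float, diameter: float) -> ROISet:
    """Three stacked discs over the organoid (ROI1 top .. ROI3 bottom)."""
    r = diameter / 2.0
    cx = width / 2.0
    return ROISet({
        "ROI1": Disc(cx, 0.75 * height, r),
        "ROI2": Disc(cx, 0.50 * height, r),
        "ROI3": Disc(cx, 0.25 * height, r),
    })


@dataclass
class ROITimeSeries:
    """Per-ROI mean concentration vs time, with running extrema."""

    times: np.ndarray
    means: dict[str, np.ndarray]
    mins: dict[str, float]
    maxs: dict[str, float]

    def __post_init__(self) -> None:
        for name, m in self.means.items():
            if not (self.mins[name] <= m.min() + 1e-12 and
                    m.max() <= self.maxs[name] + 1e-12):
                raise ValueError(f"ROI {name!r}: min <= mean <= max violated")

    def peak(self, name: str) -> float:
        return float(self.means[name].max())

    def late_mean(self, name: str, t_start: float, t_end: float | None = None) -> float:
        t = self.times
        sel = t >= t_start if t_end is None else (t >= t_start) & (t <= t_end)
        return float(self.means[name][sel].mean())

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for name, m in self.means.items():
            for t, v in zip(self.times, m):
                rows.append({"time_s": t, "roi_name": name, "mean_nM": v,
                             "min_nM": self.mins[name], "max_nM": self.maxs[name]})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def extract_roi_timeseries(history: ConcentrationHistory, rois: ROISet) -> ROITimeSeries:
    """Spatial mean of each stored field over each ROI, plus run extrema.

    Extrema are taken over the stored snapshot cadence.  Raises
    :class:`GeometryError` for ROIs outside the domain or covering no
    cell centres.
    """
    grid = history.grid
    w, h = grid.extent
    rois.validate_inside(w, h)
    x, y = grid.cell_centers()
    means: dict[str, np.ndarray] = {}
    for name, patch in rois.items():
        m = patch.mask(x, y)
        if not m.any():
            raise GeometryError(f"ROI {name!r} covers no grid cells")
        means[name] = history.fields[:, m].mean(axis=1)
    mins = {n: float(v.min()) for n, v in means.items()}
    maxs = {n: float(v.max()) for n, v in means.items()}
    return ROITimeSeries(times=history.times.copy(), means=means, mins=mins, maxs=maxs)
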