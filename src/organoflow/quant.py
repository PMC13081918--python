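"""Fluorescence-to-concentration quantification.

Camera intensity is modelled as affine in local tracer concentration,
``I = m c + b``.  A calibration curve is fitted by ordinary least squares
to aliquot images at known concentrations (R^2 is the coefficient of
determination, 1 - SS_res/SS_tot); image stacks are then inverted
per pixel via ``c = (I - b)/m`` with negative results clamped to zero and
the clamped fraction reported.  Gradient structure is summarised as
pairwise ROI concentration offsets over time and their stability (the
standard deviation of each offset over a trailing window).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, CalibrationError, GeometryError, InversionError
from .rois import ROISet

__all__ = [
    "ImageStack",
    "CalibrationCurve",
    "ConcentrationStack",
    "GradientReport",
    "fit_calibration",
    "intensity_to_concentration",
    "roi_mean_timeseries",
    "gradient_offsets",
]


@dataclass
class ImageStack:
    """Time-lapse single-channel frames with physical pixel size.

    ``frames`` has shape (T, H, W) in arbitrary non-negative intensity
    units; ``pixel_size`` is um/pixel.  Frame axis order is (row=y,
    col=x) as delivered by TIFF readers.
    """

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    channel: str = "green"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(
            path, self.frames.astype(np.float32), photometric="minisblack",
            metadata={"axes": "TYX", "pixel_size_um": self.pixel_size},
        )


@dataclass(frozen=True)
class CalibrationCurve:
    """Affine intensity/concentration map with goodness of fit."""

    slope: float            # intensity per nM
    intercept: float        # intensity at zero concentration
    r_squared: float
    conc_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope):
            raise CalibrationError("slope must be finite")
        if not (0.0 <= self.r_squared <= 1.0):
            raise CalibrationError("r_squared must lie in [0, 1]")

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"slope\t{self.slope!r}\n")
            fh.write(f"intercept\t{self.intercept!r}\n")
            fh.write(f"r_squared\t{self.r_squared!r}\n")
            fh.write(f"conc_min\t{self.conc_range[0]!r}\n")
            fh.write(f"conc_max\t{self.conc_range[1]!r}\n")

    @classmethod
    def load(cls, path) -> "CalibrationCurve":
        vals = {}
        with open(path) as fh:
            for line in fh:
                k, v = line.split("\t")
                vals[k] = float(v)
        return cls(vals["slope"], vals["intercept"], vals["r_squared"],
                   (vals["conc_min"], vals["conc_max"]))


def fit_calibration(levels, intensities) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, mean intensity).

    Needs at least three distinct concentration levels.  A constant
    response (zero intensity variance) yields slope 0 and R^2 = 0.
    """
    levels = np.asarray(levels, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if levels.shape != intensities.shape:
        raise CalibrationError("levels and intensities must have equal length")
    if np.unique(levels).size < 3:
        raise CalibrationError("need at least 3 distinct concentration levels")
    ss_tot = float(np.sum((intensities - intensities.mean()) ** 2))
    if ss_tot == 0.0:
        return CalibrationCurve(0.0, float(intensities.mean()), 0.0,
                                (float(levels.min()), float(levels.max())))
    res = stats.linregress(levels, intensities)
    pred = res.slope * levels + res.intercept
    ss_res = float(np.sum((intensities - pred) ** 2))
    r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return CalibrationCurve(float(res.slope), float(res.intercept), r2,
                            (float(levels.min()), float(levels.max())))


@dataclass
class ConcentrationStack:
    """Inverted stack (nM) plus the fraction of pixels clamped at zero."""

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_size: float
    clamped_fraction: float


def intensity_to_concentration(stack: ImageStack, curve: CalibrationCurve) -> ConcentrationStack:
    """Per-pixel inversion ``(I - intercept)/slope``, clamped below at 0."""
    if curve.slope == 0.0:
        raise InversionError("cannot invert a zero-slope calibration")
    conc = (stack.frames - curve.intercept) / curve.slope
    clamped = conc < 0.0
    frac = float(clamped.mean())
    return ConcentrationStack(np.where(clamped, 0.0, conc),
                              stack.timestamps.copy(), stack.pixel_size, frac)


def roi_mean_timeseries(stack: ImageStack | ConcentrationStack, rois: ROISet
                        ) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Mean over each ROI's pixels, per frame.  ROI coordinates are um.

    Returns ``(timestamps, {roi_name: series})``.
    """
    T, H, W = stack.frames.shape
    px = stack.pixel_size
    rois.validate_inside(W * px, H * px)
    x = (np.arange(W) + 0.5) * px
    y = (np.arange(H) + 0.5) * px
    out: dict[str, np.ndarray] = {}
    for name, patch in rois.items():
        m = patch.mask(x, y).T  # patch masks are (x, y); frames are (y, x)
        if not m.any():
            raise GeometryError(f"ROI {name!r} covers no pixels")
        out[name] = stack.frames[:, m].mean(axis=1)
    return stack.timestamps.copy(), out


@dataclass
class GradientReport:
    """Pairwise ROI offsets vs time and their trailing-window stability."""

    times: np.ndarray
    offsets: dict[tuple[str, str], np.ndarray]
    stability: dict[tuple[str, str], float]
    window: float

    def offset(self, a: str, b: str) -> np.ndarray:
        if (a, b) in self.offsets:
            return self.offsets[(a, b)]
        return -self.offsets[(b, a)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (a, b), series in self.offsets.items():
            for t, v in zip(self.times, series):
                rows.append({"time_s": t, "roi_a": a, "roi_b": b,
                             "offset_nM": v, "stability_nM": self.stability[(a, b)]})
        return pd.DataFrame(rows)


def gradient_offsets(times: np.ndarray, series: dict[str, np.ndarray],
                     window: float) -> GradientReport:
    """All pairwise ROI difference series and their stability.

    ``stability`` is the standard deviation of each offset over the
    trailing ``window`` seconds — small values mean the spatial gradient
    holds steady.  All series must share the same timestamps.
    """
    names = list(series)
    if len(names) < 2:
        raise ValueError("need at least two ROI series")
    times = np.asarray(times, dtype=float)
    span = times[-1] - times[0]
    if window > span:
        raise ValueError("window exceeds the series time span")
    n = len(times)
    for name, s in series.items():
        if len(s) != n:
            raise AlignmentError(f"series {name!r} length mismatch with timestamps")
    tail = times >= times[-1] - window
    offsets = {}
    stability = {}
    for a, b in combinations(names, 2):
        diff = np.asarray(series[a], dtype=float) - np.asarray(series[b], dtype=float)
        offsets[(a, b)] = diff
        stability[(a, b)] = float(np.std(diff[tail]))
    return GradientReport(times=times.copy(), offsets=offsets,
                          stability=stability, window=window)
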