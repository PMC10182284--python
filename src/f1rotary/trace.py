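"""Data model and I/O for single-molecule rotary traces.

A rotary trace records the angular position of a probe attached to the
rotor shaft of a molecular motor (here the gamma subunit of F1-ATPase),
sampled at a constant camera frame rate.  Angles are kept in degrees and
*unwrapped*: the series is continuous and accumulates 360 degrees per
revolution, so a processively rotating motor has a monotonically growing
angle.  Counterclockwise is the positive direction, following the F1
convention; movies mirrored in y must be flipped upstream.

Traces arrive either as (time_s, angle_deg) tables or as raw probe
centroids (time_s, x, y), in which case the polar angle about the rotation
center is computed here.  The rotation center is estimated as the mean of
all centroids; no ellipticity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    MissingColumnError,
    NonNumericDataError,
    NonUniformSamplingError,
)

__all__ = [
    "RotaryTrace",
    "read_trace",
    "write_trace",
    "angle_from_xy",
    "unwrap_angles",
    "rotation_rate",
]

#: relative tolerance on frame-period uniformity
_SPACING_RTOL = 1e-9


@dataclass
class RotaryTrace:
    """A uniformly sampled, unwrapped angular time course.

    Parameters
    ----------
    time : ndarray
        Sample times in seconds, strictly increasing with constant spacing.
    angle : ndarray
        Unwrapped probe angle in degrees (may exceed 360).
    x, y : ndarray, optional
        Raw probe centroid coordinates, arbitrary length units.
    fps : float, optional
        Frames per second.  If omitted it is derived as the reciprocal of
        the time spacing; if given it must agree with the spacing.
    meta : dict
        Free-form provenance labels (molecule id, substrate, concentration).
    """

    time: np.ndarray
    angle: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    fps: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.angle = np.asarray(self.angle, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("time must be 1-D with at least 2 samples")
        if self.angle.shape != self.time.shape:
            raise ValueError("angle and time must have equal length")
        if not np.all(np.isfinite(self.time)):
            raise NonNumericDataError("time contains non-finite values")
        if not np.all(np.isfinite(self.angle)):
            raise NonNumericDataError("angle contains non-finite values")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise NonUniformSamplingError("time must be strictly increasing")
        period = float(np.median(dt))
        if np.any(np.abs(dt - period) > _SPACING_RTOL * period + 1e-15):
            raise NonUniformSamplingError(
                f"non-uniform sampling: spacing varies beyond rtol={_SPACING_RTOL}"
            )
        derived_fps = 1.0 / period
        if self.fps is None:
            self.fps = derived_fps
        elif not np.isclose(self.fps, derived_fps, rtol=1e-6):
            raise NonUniformSamplingError(
                f"fps={self.fps} disagrees with time spacing (1/dt={derived_fps})"
            )
        for name in ("x", "y"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time.shape:
                    raise ValueError(f"{name} must match time length")
                setattr(self, name, v)

    def __len__(self) -> int:
        return self.time.size

    @property
    def duration(self) -> float:
        """Span of the trace in seconds."""
        return float(self.time[-1] - self.time[0])


def angle_from_xy(
    x: np.ndarray,
    y: np.ndarray,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Polar angle of probe centroids about the rotation center.

    When ``center`` is omitted it is estimated as the arithmetic mean of
    the points.  Angles are counterclockwise-positive and wrapped to
    [0, 360).

    Raises
    ------
    DegenerateGeometryError
        If every point coincides with the center.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with >= 2 points")
    if center is None:
        center = (float(np.mean(x)), float(np.mean(y)))
    dx = x - center[0]
    dy = y - center[1]
    if np.all((dx == 0) & (dy == 0)):
        raise DegenerateGeometryError("all points coincide with the center")
    ang = np.degrees(np.arctan2(dy, dx))
    return np.mod(ang, 360.0)


def unwrap_angles(wrapped: np.ndarray) -> np.ndarray:
    """Remove 360-degree jumps from a wrapped angle series.

    The output differs from the input by an integer multiple of 360 at each
    sample, and consecutive output differences lie in (-180, 180].
    """
    wrapped = np.asarray(wrapped, dtype=float)
    return np.degrees(np.unwrap(np.radians(wrapped)))


def rotation_rate(trace: RotaryTrace) -> float:
    """Bulk rotation rate in revolutions per second.

    Estimated as the least-squares slope of (angle / 360) against time,
    which is robust to partial final turns (unlike revolution counting).
    """
    if len(trace) < 3:
        raise ValueError("rotation_rate requires at least 3 samples")
    slope = np.polynomial.polynomial.polyfit(trace.time, trace.angle / 360.0, 1)[1]
    return float(slope)


_TIME_COL = "time_s"
_ANGLE_COL = "angle_deg"
_XY_COLS = ("x", "y")


def read_trace(
    path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> RotaryTrace:
    """Read a rotary trace from a delimited text file.

    The file must have a header row and either (time_s, angle_deg) or
    (time_s, x, y) columns; a ``dialect`` mapping may rename logical
    columns to the file's actual headers, e.g. ``{"time_s": "t"}``.
    Comma and tab separators are auto-detected unless ``sep`` is given.

    When centroids are supplied the angle is computed with
    :func:`angle_from_xy` (mean-centered) and unwrapped.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    if _TIME_COL not in df.columns:
        raise MissingColumnError(f"missing required column '{_TIME_COL}'")
    have_angle = _ANGLE_COL in df.columns
    have_xy = all(c in df.columns for c in _XY_COLS)
    if not (have_angle or have_xy):
        raise MissingColumnError(
            f"need either '{_ANGLE_COL}' or both of {_XY_COLS} columns"
        )
    cols = [_TIME_COL] + ([_ANGLE_COL] if have_angle else list(_XY_COLS))
    num = df[cols].apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = num.columns[num.isna().any()].tolist()
        raise NonNumericDataError(f"non-numeric cells in column(s) {bad}")
    time = num[_TIME_COL].to_numpy()
    if have_angle:
        return RotaryTrace(time=time, angle=num[_ANGLE_COL].to_numpy())
    x = num["x"].to_numpy()
    y = num["y"].to_numpy()
    angle = unwrap_angles(angle_from_xy(x, y))
    return RotaryTrace(time=time, angle=angle, x=x, y=y)


def write_trace(trace: RotaryTrace, path, sep: str = ",") -> None:
    """Write a trace as delimited text (inverse of :func:`read_trace`)."""
    cols = {_TIME_COL: trace.time, _ANGLE_COL: trace.angle}
    if trace.x is not None and trace.y is not None:
        cols["x"] = trace.x
        cols["y"] = trace.y
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False, float_format="%.10g")
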