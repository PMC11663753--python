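"""Strain time series from tracked endocardial contours, and peak detection.

Strain here is length-based Lagrangian strain on a tracked endocardial
contour: the percent change of the contour polyline length relative to the
end-diastolic (first-frame) reference.  Shortening is negative by
convention; reported global strains are magnitudes.  Feature tracking
itself is out of scope — this module consumes its output (point-corresponded
contours per time phase) or directly supplied strain curves.
"""
from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .walls import View, WallRegion

STRAIN_COLUMNS = ["patient_id", "view", "wall", "frame", "time_ms", "strain_pct"]
CONTOUR_COLUMNS = ["patient_id", "view", "wall", "frame", "point_index",
                   "x_mm", "y_mm"]


@dataclass
class ContourSequence:
    """Tracked endocardial contour of one wall across the cardiac cycle.

    ``frames[k]`` is an (n_points, 2) array of coordinates in mm at time
    ``times[k]``; points correspond across frames (same count and order).
    """

    view: View
    wall: WallRegion
    frames: list[np.ndarray]
    times: np.ndarray  # ms, strictly increasing, times[0] == 0

    def __post_init__(self):
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times lengths differ")
        if len(self.frames) < 2:
            raise ValueError("need at least 2 frames")
        npts = {f.shape for f in self.frames}
        if len(npts) != 1:
            raise ValueError("point count must match at every frame")
        if self.frames[0].ndim != 2 or self.frames[0].shape[1] != 2:
            raise ValueError("each frame must be an (n, 2) coordinate array")
        if self.frames[0].shape[0] < 2:
            raise ValueError("need at least 2 points per frame")
        if self.times[0] != 0:
            raise ValueError("times must start at 0 (end-diastole)")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_phases(self) -> int:
        return len(self.frames)


@dataclass
class StrainSeries:
    """One wall's strain-vs-time curve over a single cardiac cycle."""

    view: View
    wall: WallRegion
    direction: str          # "longitudinal" | "circumferential"
    times: np.ndarray       # ms
    values: np.ndarray      # % signed; negative = shortening
    rr_interval: float      # ms
    frame_duration: float   # ms = rr_interval / n_phases

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values lengths differ")
        if self.times[0] != 0 or self.values[0] != 0:
            raise ValueError("end-diastolic reference requires "
                             "times[0] == 0 and values[0] == 0")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.rr_interval <= 0 or self.frame_duration <= 0:
            raise ValueError("rr_interval and frame_duration must be > 0")

    @property
    def n_phases(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class PeakEvent:
    """Peak (maximum-magnitude) strain of one series."""

    time_to_peak: float   # ms from the R wave
    peak_value: float     # % signed
    peak_magnitude: float  # % = |peak_value|
    frame_index: int


class NoPeakError(ValueError):
    """Raised for an all-zero series (untracked wall)."""


def contour_length(points) -> float:
    """Polyline length (mm) of an ordered 2D point list."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def direction_for_view(view: View) -> str:
    return "circumferential" if view is View.SAX else "longitudinal"


def compute_contour_strain(contours: ContourSequence,
                           rr_interval: float | None = None) -> StrainSeries:
    """Length-based Lagrangian strain of a tracked contour.

    values[t] = 100 * (L(t) - L(0)) / L(0) with L the contour polyline
    length; longitudinal in the long-axis views, circumferential in SAX.
    When ``rr_interval`` is omitted it is taken as n_phases * frame spacing
    (a uniform grid spanning the full cycle).
    """
    lengths = np.array([contour_length(f) for f in contours.frames])
    if lengths[0] == 0:
        raise ValueError("degenerate reference contour (zero length)")
    values = 100.0 * (lengths - lengths[0]) / lengths[0]
    values[0] = 0.0
    dt = float(contours.times[1] - contours.times[0])
    rr = float(rr_interval) if rr_interval is not None else dt * contours.n_phases
    return StrainSeries(
        view=contours.view, wall=contours.wall,
        direction=direction_for_view(contours.view),
        times=contours.times.copy(), values=values,
        rr_interval=rr, frame_duration=rr / contours.n_phases)


def detect_peak(series: StrainSeries) -> PeakEvent:
    """Peak strain as the maximum-magnitude frame, excluding frame 0.

    Frame 0 is the end-diastolic reference where strain is identically
    zero.  Ties are broken toward the earliest frame.  The search stays on
    the native frame grid: the PSC rule is stated in units of one
    timeframe, which is only meaningful there.
    """
    if series.n_phases < 3:
        raise ValueError("need at least 3 frames for peak detection")
    mags = np.abs(series.values[1:])
    if np.all(mags == 0):
        raise NoPeakError(f"all-zero strain series for wall {series.wall}")
    idx = 1 + int(np.argmax(mags))  # argmax returns first of ties
    return PeakEvent(
        time_to_peak=float(series.times[idx]),
        peak_value=float(series.values[idx]),
        peak_magnitude=float(abs(series.values[idx])),
        frame_index=idx)


def global_view_strain(series_list: Sequence[StrainSeries]) -> float:
    """View-level global strain: mean peak magnitude over the view's walls.

    Reported positive, as global longitudinal/circumferential strain values
    conventionally are in tabulated summaries.
    """
    if len(series_list) == 0:
        raise ValueError("need at least one series")
    views = {s.view for s in series_list}
    if len(views) != 1:
        raise ValueError(f"mixed views: {sorted(v.value for v in views)}")
    return float(np.mean([detect_peak(s).peak_magnitude for s in series_list]))


def average_series(series_list: Sequence[StrainSeries],
                   wall: WallRegion | None = None) -> StrainSeries:
    """Point-wise mean of strain series on a common time grid.

    Used both to merge segmental curves into a wall curve and to build the
    RV3ch free-wall representative (anterior + inferior mean) for PSC.
    """
    if len(series_list) == 0:
        raise ValueError("need at least one series")
    first = series_list[0]
    for s in series_list[1:]:
        if not np.allclose(s.times, first.times):
            raise ValueError("series must share a time grid")
        if s.view is not first.view:
            raise ValueError("series must share a view")
    values = np.mean([s.values for s in series_list], axis=0)
    values[0] = 0.0
    return StrainSeries(
        view=first.view, wall=wall if wall is not None else first.wall,
        direction=first.direction, times=first.times.copy(), values=values,
        rr_interval=first.rr_interval, frame_duration=first.frame_duration)


# ---------------------------------------------------------------------------
# CSV interchange (long format)

def write_strain_csv(strain: Mapping[str, Mapping[WallRegion, StrainSeries]],
                     path) -> None:
    """Write per-patient, per-wall series to the long-format strain CSV."""
    rows = []
    for pid in strain:
        for wall, s in strain[pid].items():
            for k in range(s.n_phases):
                rows.append((pid, s.view.value, wall.csv_name, k,
                             s.times[k], s.values[k]))
    df = pd.DataFrame(rows, columns=STRAIN_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6g")


def read_strain_csv(path) -> dict[str, dict[WallRegion, StrainSeries]]:
    """Read the long-format strain CSV into per-patient wall series.

    The RR interval is reconstructed as n_frames * frame spacing (the grid
    covers one full cycle).
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in STRAIN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"strain CSV missing columns: {missing}")
    out: dict[str, dict[WallRegion, StrainSeries]] = {}
    for (pid, view_s, wall_s), grp in df.groupby(
            ["patient_id", "view", "wall"], sort=False):
        view = View.parse(view_s)
        wall = WallRegion.from_csv(view, wall_s)
        grp = grp.sort_values("frame")
        times = grp["time_ms"].to_numpy(dtype=float)
        values = grp["strain_pct"].to_numpy(dtype=float)
        values[0] = 0.0  # guard rounding of the reference frame on write
        dt = times[1] - times[0]
        rr = dt * len(times)
        out.setdefault(pid, {})[wall] = StrainSeries(
            view=view, wall=wall, direction=direction_for_view(view),
            times=times, values=values, rr_interval=rr,
            frame_duration=dt)
    return out


def read_contour_csv(path) -> dict[str, dict[WallRegion, ContourSequence]]:
    """Read the long-format tracked-contour CSV."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in CONTOUR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contour CSV missing columns: {missing}")
    out: dict[str, dict[WallRegion, ContourSequence]] = {}
    for (pid, view_s, wall_s), grp in df.groupby(
            ["patient_id", "view", "wall"], sort=False):
        view = View.parse(view_s)
        wall = WallRegion.from_csv(view, wall_s)
        frames, times = [], []
        for frame_idx, fgrp in grp.groupby("frame", sort=True):
            fgrp = fgrp.sort_values("point_index")
            frames.append(fgrp[["x_mm", "y_mm"]].to_numpy(dtype=float))
            times.append(float(fgrp["time_ms"].iloc[0]))
        out.setdefault(pid, {})[wall] = ContourSequence(
            view=view, wall=wall, frames=frames, times=np.asarray(times))
    return out
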