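"""The two core statistics: the multi-view dyssynchrony index and PSC.

Mechanical dyssynchrony is quantified as the standard deviation of
time-to-peak strain across the RV wall regions of a view set, expressed as
a percentage of the RR interval.  Post-systolic contraction (PSC) is peak
strain occurring more than one timeframe after pulmonary valve closure;
its duration is the signed difference between time of peak strain and the
closure time, in ms and as a percentage of RR.
"""
from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import PatientRecord
from .strain import (NoPeakError, PeakEvent, StrainSeries, average_series,
                     detect_peak)
from .walls import (PSC_REPRESENTATIVE, VIEW_SET_WALLS, View, ViewSet,
                    ViewSetLabel, WallRegion, select_view_set)

METRICS_COLUMNS = [
    "patient_id", "dys3_pct", "dys2_pct", "dys1_4ch_pct", "dys1_rv3ch_pct",
    "psc_rv3ch", "psc_4ch", "psc_sax",
    "tpsc_rv3ch_ms", "tpsc_4ch_ms", "tpsc_sax_ms",
    "tpsc_rv3ch_pctrr", "tpsc_4ch_pctrr", "tpsc_sax_pctrr",
    "gls_rv3ch", "gls_4ch", "gcs_sax",
]

_DYS_COLUMN = {
    ViewSetLabel.THREE_VIEW: "dys3_pct",
    ViewSetLabel.TWO_VIEW: "dys2_pct",
    ViewSetLabel.ONE_VIEW_4CH: "dys1_4ch_pct",
    ViewSetLabel.ONE_VIEW_RV3CH: "dys1_rv3ch_pct",
}

_VIEW_KEY = {View.RV3CH: "rv3ch", View.CH4: "4ch", View.SAX: "sax"}


@dataclass(frozen=True)
class DyssynchronyResult:
    """SD of time-to-peak over a wall set, indexed to the RR interval."""

    view_set: ViewSet
    ttp_by_wall: dict
    sd_ms: float
    index_pct: float      # 100 * sd_ms / rr_interval
    rr_interval: float
    n_walls: int


@dataclass(frozen=True)
class PSCResult:
    """Presence and signed duration of post-systolic contraction in a view."""

    view: View
    present: int
    t_peak: float          # ms
    pvc_time: float        # ms
    duration_ms: float     # signed, t_peak - pvc_time
    duration_pct_rr: float
    frame_duration: float


def dyssynchrony_index(ttp_by_wall: Mapping[WallRegion, float],
                       rr_interval: float,
                       view_set: ViewSet,
                       ddof: int = 1) -> DyssynchronyResult:
    """Dyssynchrony index over one view set.

    ``sd_ms`` is the sample (n-1 denominator) standard deviation of the
    wall time-to-peak values; ``ddof=0`` switches to the population form.
    The index is 100 * sd_ms / RR.
    """
    if rr_interval <= 0:
        raise ValueError("rr_interval must be > 0")
    walls = frozenset(ttp_by_wall)
    if walls != view_set.walls:
        raise ValueError(
            f"wall set mismatch: got {sorted(w.value for w in walls)} "
            f"for {view_set.label.value}")
    if len(walls) < 2:
        raise ValueError("need at least 2 walls")
    ttp = np.array([float(ttp_by_wall[w]) for w in sorted(walls)])
    if np.any((ttp <= 0) | (ttp > rr_interval)):
        raise ValueError("every time-to-peak must lie in (0, RR]")
    sd = float(np.std(ttp, ddof=ddof))
    return DyssynchronyResult(
        view_set=view_set, ttp_by_wall=dict(ttp_by_wall), sd_ms=sd,
        index_pct=100.0 * sd / rr_interval, rr_interval=float(rr_interval),
        n_walls=len(walls))


def detect_psc(peak: PeakEvent, pvc_time: float, frame_duration: float,
               rr_interval: float, view: Optional[View] = None) -> PSCResult:
    """Classify post-systolic contraction from a peak event.

    PSC is present when the peak falls strictly more than one timeframe
    after pulmonary valve closure; the duration t_peak - pvc is reported
    signed for every patient (negative for pre-closure peaks).
    """
    if not (0 < pvc_time < rr_interval):
        raise ValueError("pvc_time must lie in (0, RR)")
    if frame_duration <= 0:
        raise ValueError("frame_duration must be > 0")
    duration = peak.time_to_peak - pvc_time
    return PSCResult(
        view=view, present=int(duration > frame_duration),
        t_peak=peak.time_to_peak, pvc_time=pvc_time,
        duration_ms=duration,
        duration_pct_rr=100.0 * duration / rr_interval,
        frame_duration=frame_duration)


@dataclass
class PatientMetrics:
    """Flat per-patient record of all strain-derived metrics.

    ``None`` marks a metric whose inputs were unavailable (missing view or
    untracked wall); ``flags`` records which view sets were skipped and
    whether the two-view fallback fired.
    """

    patient_id: str
    dyssynchrony: dict = field(default_factory=dict)   # ViewSetLabel -> DyssynchronyResult
    psc: dict = field(default_factory=dict)            # View -> PSCResult
    global_strain: dict = field(default_factory=dict)  # View -> % magnitude
    flags: list = field(default_factory=list)

    def to_row(self) -> dict:
        row = {c: None for c in METRICS_COLUMNS}
        row["patient_id"] = self.patient_id
        for label, res in self.dyssynchrony.items():
            row[_DYS_COLUMN[label]] = res.index_pct
        for view, res in self.psc.items():
            k = _VIEW_KEY[view]
            row[f"psc_{k}"] = res.present
            row[f"tpsc_{k}_ms"] = res.duration_ms
            row[f"tpsc_{k}_pctrr"] = res.duration_pct_rr
        for view, g in self.global_strain.items():
            col = {"RV3ch": "gls_rv3ch", "4ch": "gls_4ch",
                   "SAX": "gcs_sax"}[view.value]
            row[col] = g
        return row


def patient_metrics(patient: PatientRecord,
                    strain: Mapping[WallRegion, StrainSeries]) -> PatientMetrics:
    """All per-patient metrics from one patient's wall strain series.

    Computes a peak per wall, then the dyssynchrony index for every view
    set whose walls all yielded peaks, PSC per available view on the
    free-wall representative curve, and view-average global strain.
    Untracked walls propagate as missing values with a flag rather than
    an error.
    """
    out = PatientMetrics(patient_id=patient.patient_id)
    peaks: dict[WallRegion, PeakEvent] = {}
    for wall, series in strain.items():
        try:
            peaks[wall] = detect_peak(series)
        except NoPeakError:
            out.flags.append(f"no_peak:{wall.value}")

    rr = patient.rr_interval
    walls_present = set(peaks)

    primary = None
    try:
        primary = select_view_set(patient.available_views)
    except ValueError:
        out.flags.append("no_usable_view")
    if primary is not None and primary.fallback:
        out.flags.append(f"fallback:{primary.label.value}")

    for label, wall_set in VIEW_SET_WALLS.items():
        if wall_set <= walls_present:
            vs = ViewSet(label, fallback=(primary is not None
                                          and label is primary.label
                                          and primary.fallback))
            ttp = {w: peaks[w].time_to_peak for w in wall_set}
            out.dyssynchrony[label] = dyssynchrony_index(ttp, rr, vs)
        else:
            out.flags.append(f"skipped:{label.value}")

    for view in patient.available_views:
        walls = PSC_REPRESENTATIVE[view]
        series = [strain[w] for w in walls
                  if w in strain and w in peaks]
        pvc = patient.pvc_for_view(view)
        if not series or pvc is None:
            out.flags.append(f"psc_unavailable:{view.value}")
            continue
        rep = series[0] if len(series) == 1 else average_series(series)
        try:
            peak = detect_peak(rep)
        except NoPeakError:
            out.flags.append(f"psc_unavailable:{view.value}")
            continue
        out.psc[view] = detect_psc(peak, pvc, rep.frame_duration,
                                   rr, view=view)

    for view in patient.available_views:
        view_series = [strain[w] for w in strain
                       if w.view is view and w in peaks]
        if view_series:
            out.global_strain[view] = float(np.mean(
                [peaks[s.wall].peak_magnitude for s in view_series]))
    return out


def metrics_table(cohort, strain_by_patient) -> pd.DataFrame:
    """Metrics CSV table: one row per patient, missing values left empty."""
    rows = []
    for p in cohort:
        m = patient_metrics(p, strain_by_patient.get(p.patient_id, {}))
        rows.append(m.to_row())
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_metrics_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in METRICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics CSV missing columns: {missing}")
    return df
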