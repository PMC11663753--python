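"""Patient and cohort domain types, clinical derived quantities, and filters.

A :class:`PatientRecord` carries the timing quantities needed by the strain
pipeline (RR interval, phases per cycle, pulmonary-valve-closure time), the
survival outcome (death or lung transplantation, follow-up in months), and
optional hemodynamics from right-heart catheterization (RHC).
"""
from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Collection, Mapping
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .walls import View

#: Exact column order of the cohort CSV interchange schema.
COHORT_COLUMNS = [
    "patient_id", "age_years", "sex", "rr_ms", "n_phases",
    "pvc_rvot_ms", "pvc_rv3ch_ms", "pvc_sax_ms", "pvc_source",
    "views_available", "event", "followup_months", "incident",
    "mpap", "pawp", "co_lmin", "pvr_wu", "mrap",
    "days_rhc_to_cmr", "medication_change",
    "fibrosis_insertion", "fibrosis_septal", "fibrosis_lateral", "rvef",
]

#: Named clinical exclusion criteria; the view-count rule is derived.
EXCLUSION_REASONS = (
    "septal_defect", "atrial_fibrillation", "valvular_disease",
    "image_quality", "insufficient_views",
)


@dataclass
class PatientRecord:
    """One patient's clinical, timing, and outcome data."""

    patient_id: str
    age: float                      # years; cohort restricted to > 16 y
    sex: str                        # "female" | "male"
    rr_interval: float              # ms
    n_phases: int                   # reconstructed time phases per cycle
    pvc_rvot_ms: Optional[float] = None
    pvc_rv3ch_ms: Optional[float] = None
    pvc_sax_ms: Optional[float] = None
    pvc_source: str = "RVOT"        # where closure time was measured
    available_views: frozenset = frozenset()
    event: int = 0                  # death or lung transplantation
    followup_time: float = 0.0      # months
    incident: Optional[int] = None  # imaged at diagnosis vs prevalent
    mpap: Optional[float] = None    # mmHg
    pawp: Optional[float] = None    # mmHg
    cardiac_output: Optional[float] = None  # L/min
    pvr: Optional[float] = None     # Wood units
    mrap: Optional[float] = None    # mmHg
    days_rhc_to_cmr: Optional[float] = None
    medication_change: Optional[int] = None
    fibrosis_insertion: Optional[int] = None
    fibrosis_septal: Optional[int] = None
    fibrosis_lateral: Optional[int] = None
    rvef: Optional[float] = None    # %

    def __post_init__(self):
        self.available_views = frozenset(
            v if isinstance(v, View) else View.parse(v)
            for v in self.available_views)
        self.validate()

    def validate(self) -> None:
        if self.rr_interval <= 0:
            raise ValueError(f"{self.patient_id}: rr_interval must be > 0")
        if self.n_phases < 8:
            raise ValueError(f"{self.patient_id}: n_phases must be >= 8")
        if self.age < 16:
            raise ValueError(f"{self.patient_id}: age must be >= 16 years")
        if self.followup_time < 0:
            raise ValueError(f"{self.patient_id}: followup_time must be >= 0")
        if self.sex not in ("female", "male"):
            raise ValueError(f"{self.patient_id}: sex must be female|male")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0 or 1")
        for name in ("pvc_rvot_ms", "pvc_rv3ch_ms", "pvc_sax_ms"):
            val = getattr(self, name)
            if val is not None and not (0 < val < self.rr_interval):
                raise ValueError(
                    f"{self.patient_id}: {name}={val} outside (0, RR)")

    @property
    def frame_duration(self) -> float:
        """Duration of one reconstructed time phase (ms), RR / n_phases."""
        return self.rr_interval / self.n_phases

    def pvc_for_view(self, view: View) -> Optional[float]:
        """Pulmonary-valve-closure time for a view.

        A view-specific measurement takes precedence; otherwise the RVOT
        value is used for every view (closure is a single physiologic event;
        the alternative sources only record measurement provenance).
        """
        specific = {View.RV3CH: self.pvc_rv3ch_ms, View.SAX: self.pvc_sax_ms}
        val = specific.get(view)
        return val if val is not None else self.pvc_rvot_ms


@dataclass
class CohortTable:
    """Ordered collection of patients with generation/schema metadata."""

    patients: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [p.patient_id for p in self.patients]
        dupes = [i for i, c in Counter(ids).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            rows.append({
                "patient_id": p.patient_id,
                "age_years": p.age,
                "sex": p.sex,
                "rr_ms": p.rr_interval,
                "n_phases": p.n_phases,
                "pvc_rvot_ms": p.pvc_rvot_ms,
                "pvc_rv3ch_ms": p.pvc_rv3ch_ms,
                "pvc_sax_ms": p.pvc_sax_ms,
                "pvc_source": p.pvc_source,
                "views_available": ";".join(
                    v.value for v in sorted(p.available_views,
                                            key=lambda v: v.value)),
                "event": p.event,
                "followup_months": p.followup_time,
                "incident": p.incident,
                "mpap": p.mpap,
                "pawp": p.pawp,
                "co_lmin": p.cardiac_output,
                "pvr_wu": p.pvr,
                "mrap": p.mrap,
                "days_rhc_to_cmr": p.days_rhc_to_cmr,
                "medication_change": p.medication_change,
                "fibrosis_insertion": p.fibrosis_insertion,
                "fibrosis_septal": p.fibrosis_septal,
                "fibrosis_lateral": p.fibrosis_lateral,
                "rvef": p.rvef,
            })
        return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def compute_pvr(mpap: float, pawp: float, cardiac_output: float) -> float:
    """Pulmonary vascular resistance in Wood units, (mPAP - PAWP) / CO.

    Raises
    ------
    ValueError
        If cardiac output is not positive, or wedge pressure exceeds mean
        pulmonary artery pressure (implausible hemodynamics).
    """
    if cardiac_output <= 0:
        raise ValueError("cardiac output must be > 0 L/min")
    if pawp < 0 or mpap < pawp:
        raise ValueError("require mPAP >= PAWP >= 0 mmHg")
    return (mpap - pawp) / cardiac_output


def hemodynamic_subgroup(cohort: CohortTable, max_days: float = 30) -> CohortTable:
    """Patients eligible for the strain-vs-hemodynamics association analysis.

    Retains patients with at most ``max_days`` (inclusive, absolute
    difference) between RHC and CMR and no medication change between the
    two; patients missing either field are excluded.  The input cohort is
    not modified.
    """
    kept = [p for p in cohort
            if p.days_rhc_to_cmr is not None
            and p.medication_change is not None
            and abs(p.days_rhc_to_cmr) <= max_days
            and p.medication_change == 0]
    meta = dict(cohort.metadata)
    meta["filter"] = f"hemodynamic_subgroup(max_days={max_days})"
    return CohortTable([dataclasses.replace(p) for p in kept], meta)


def apply_exclusions(
    cohort: CohortTable,
    flags: Mapping[str, Collection[str]] | None = None,
) -> tuple[CohortTable, dict[str, int]]:
    """Remove patients flagged for a study exclusion criterion.

    ``flags`` maps patient_id to the clinical exclusion reasons that apply
    (septal defect, atrial fibrillation, significant valvular disease,
    insufficient image quality).  Independently of the flags, any patient
    with fewer than two of the three RV views available is excluded.

    Returns the filtered cohort and a count per exclusion reason; a patient
    excluded for several reasons is counted under each.
    """
    flags = flags or {}
    unknown = {r for rs in flags.values() for r in rs} - set(EXCLUSION_REASONS)
    if unknown:
        raise ValueError(f"unknown exclusion reasons: {sorted(unknown)}")
    report = Counter()
    kept: list[PatientRecord] = []
    for p in cohort:
        reasons = set(flags.get(p.patient_id, ()))
        if len(p.available_views) < 2:
            reasons.add("insufficient_views")
        if reasons:
            report.update(reasons)
        else:
            kept.append(dataclasses.replace(p))
    meta = dict(cohort.metadata)
    meta["exclusions_applied"] = True
    return CohortTable(kept, meta), dict(report)


# ---------------------------------------------------------------------------
# CSV interchange

def write_cohort_csv(cohort: CohortTable, path) -> None:
    df = cohort.to_dataframe()
    df.to_csv(path, index=False, float_format="%.6g")


def _opt(row, col, cast=float):
    val = row[col]
    if pd.isna(val) or val == "":
        return None
    return cast(val)


def read_cohort_csv(path) -> CohortTable:
    """Read the cohort CSV schema; every record is validated on load."""
    df = pd.read_csv(path, dtype={"patient_id": str, "sex": str,
                                  "pvc_source": str, "views_available": str})
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    patients = []
    for _, row in df.iterrows():
        views = row["views_available"]
        views = [] if pd.isna(views) or views == "" else views.split(";")
        patients.append(PatientRecord(
            patient_id=str(row["patient_id"]),
            age=float(row["age_years"]),
            sex=str(row["sex"]),
            rr_interval=float(row["rr_ms"]),
            n_phases=int(row["n_phases"]),
            pvc_rvot_ms=_opt(row, "pvc_rvot_ms"),
            pvc_rv3ch_ms=_opt(row, "pvc_rv3ch_ms"),
            pvc_sax_ms=_opt(row, "pvc_sax_ms"),
            pvc_source=str(row["pvc_source"]),
            available_views=frozenset(views),
            event=int(row["event"]),
            followup_time=float(row["followup_months"]),
            incident=_opt(row, "incident", int),
            mpap=_opt(row, "mpap"),
            pawp=_opt(row, "pawp"),
            cardiac_output=_opt(row, "co_lmin"),
            pvr=_opt(row, "pvr_wu"),
            mrap=_opt(row, "mrap"),
            days_rhc_to_cmr=_opt(row, "days_rhc_to_cmr"),
            medication_change=_opt(row, "medication_change", int),
            fibrosis_insertion=_opt(row, "fibrosis_insertion", int),
            fibrosis_septal=_opt(row, "fibrosis_septal", int),
            fibrosis_lateral=_opt(row, "fibrosis_lateral", int),
            rvef=_opt(row, "rvef"),
        ))
    return CohortTable(patients)
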