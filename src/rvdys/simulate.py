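"""Synthetic PAH cohort generator with controllable dyssynchrony and PSC.

The generator emulates the statistical structure the analysis pipeline
assumes, not cardiac mechanics: each wall's strain curve is a smooth
raised-cosine shortening bump whose depth sets the wall's peak strain and
whose center sets the wall's time-to-peak.  A per-patient latent
dyssynchrony level ``D`` (percent of RR) displaces the six wall peaks with
standardized offsets, so the realized six-wall time-to-peak SD equals
``RR * D / 100`` exactly before grid sampling — making ``D`` recoverable
by the downstream index and parameter recovery a sharp test.  Event times
follow an exponential proportional-hazards model in ``D`` and age, with
censoring from uniform study entry against an administrative horizon.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, PatientRecord, compute_pvr
from .strain import StrainSeries, direction_for_view
from .walls import PSC_REPRESENTATIVE, View, WallRegion

SCHEMA_VERSION = "1"

#: Fixed wall order used when assigning standardized peak-time offsets.
WALL_ORDER = [WallRegion.RV3CH_ANTERIOR, WallRegion.RV3CH_INFERIOR,
              WallRegion.CH4_LATERAL, WallRegion.CH4_SEPTAL,
              WallRegion.SAX_FREE, WallRegion.SAX_SEPTAL]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with cohort-calibrated defaults.

    Defaults reproduce the headline cohort structure: heart rate
    78 +/- 13 bpm, age 58 +/- 19 y (>= 16), 66% women, 25 phases per
    cycle, three-view dyssynchrony level 9 +/- 3% of RR, view-level global
    strain magnitudes ~14-15% longitudinal and ~9% circumferential, ~60%
    events with median follow-up near 37 months, and an RV3ch view missing
    in ~39% of patients.
    """

    n: int = 101
    seed: int = 0
    # biometrics
    hr_mean: float = 78.0     # bpm
    hr_sd: float = 13.0
    hr_min: float = 40.0
    hr_max: float = 140.0
    age_mean: float = 58.0    # years
    age_sd: float = 19.0
    age_min: float = 16.0
    age_max: float = 95.0
    female_fraction: float = 0.66
    n_phases: int = 25
    # strain curve shape
    amp_rv3ch: float = 14.2   # mean peak strain magnitude per wall, %
    amp_4ch: float = 14.8
    amp_sax: float = 8.7
    amp_sd: float = 3.0
    amp_min: float = 2.0
    width_frac: float = 0.8   # full bump width as fraction of RR
    tau_frac: float = 0.46    # mean time-to-peak as fraction of RR
    systole_frac: float = 0.42  # pulmonary valve closure at s * RR
    noise_sd: float = 0.3     # strain measurement noise, % strain
    # dyssynchrony level D (percent of RR), truncated at 0
    dys_mean: float = 9.0
    dys_sd: float = 3.0
    # forced PSC injection (None: prevalence emerges from timing geometry)
    psc_prob_rv3ch: Optional[float] = None
    psc_prob_4ch: Optional[float] = None
    psc_prob_sax: Optional[float] = None
    psc_shift_ms: float = 20.0
    # proportional-hazards outcome model
    h0: float = 5.0e-4        # baseline hazard per month
    beta_dys: float = math.log(1.10)   # log-hazard per % dyssynchrony
    beta_age: float = math.log(1.04)   # log-hazard per year of age
    horizon_months: float = 180.0      # administrative end of follow-up
    accrual_months: float = 176.0      # uniform entry window before horizon
    event_target: float = 0.60         # documented target event fraction
    # missingness and covariates
    rv3ch_missing_frac: float = 0.386
    incident_fraction: float = 0.72
    mpap_mean: float = 48.0
    mpap_sd: float = 14.0
    pawp_mean: float = 8.0
    pawp_sd: float = 4.0
    co_mean: float = 4.2      # L/min
    co_sd: float = 1.2
    mrap_mean: float = 8.0
    mrap_sd: float = 6.0
    days_rhc_scale: float = 15.0       # exponential scale of |RHC - CMR| gap
    med_change_prob: float = 0.35
    fibrosis_insertion_prob: float = 0.82
    fibrosis_septal_prob: float = 0.06
    fibrosis_lateral_prob: float = 0.09
    rvef_mean: float = 35.0
    rvef_sd: float = 12.0
    pvc_source_probs: tuple = (0.88, 0.05, 0.07)  # RVOT, RV3ch, SAX

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("config field 'n' must be >= 2")
        for name in ("hr_sd", "age_sd", "amp_sd", "dys_sd", "noise_sd",
                     "psc_shift_ms", "mpap_sd", "pawp_sd", "co_sd",
                     "mrap_sd", "rvef_sd", "days_rhc_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"config field {name!r} must be >= 0")
        for name in ("amp_rv3ch", "amp_4ch", "amp_sax", "width_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be > 0")
        if not (0 < self.systole_frac < 1):
            raise ValueError("config field 'systole_frac' must be in (0, 1)")
        if not (0 <= self.female_fraction <= 1):
            raise ValueError("config field 'female_fraction' must be in [0, 1]")
        if self.h0 <= 0:
            raise ValueError("config field 'h0' must be > 0")
        if self.n_phases < 8:
            raise ValueError("config field 'n_phases' must be >= 8")
        for name in ("psc_prob_rv3ch", "psc_prob_4ch", "psc_prob_sax",
                     "rv3ch_missing_frac"):
            v = getattr(self, name)
            if v is not None and not (0 <= v <= 1):
                raise ValueError(f"config field {name!r} must be in [0, 1]")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()

    @classmethod
    def from_yaml(cls, path, seed: Optional[int] = None) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for req in ("n", "seed"):
            if req not in raw:
                raise ValueError(f"missing required config field {req!r}")
        if "pvc_source_probs" in raw:
            raw["pvc_source_probs"] = tuple(raw["pvc_source_probs"])
        cfg = cls(**raw)
        if seed is not None:
            cfg.seed = int(seed)
        cfg.validate()
        return cfg


@dataclass
class SimulatedCohort:
    """A generated cohort: patient table, strain curves, and the latents."""

    cohort: CohortTable
    strain: dict                  # patient_id -> {WallRegion: StrainSeries}
    latents: pd.DataFrame         # per-patient D, realized tau, PSC forcing
    config: SimulationConfig


def _trunc_normal(rng, mean, sd, low=-np.inf, high=np.inf, size=None):
    """Truncated normal by rejection; exact and rng-deterministic."""
    if sd == 0:
        val = np.full(size if size is not None else (), mean, dtype=float)
        return float(val) if size is None else val
    shape = (size,) if isinstance(size, int) else (1,) if size is None else size
    out = np.empty(shape, dtype=float)
    mask = np.ones(shape, dtype=bool)
    while mask.any():
        draw = rng.normal(mean, sd, size=int(mask.sum()))
        ok = (draw >= low) & (draw <= high)
        idx = np.flatnonzero(mask)
        out.flat[idx[ok]] = draw[ok]
        mask.flat[idx[ok]] = False
    return float(out[0]) if size is None else out


def raised_cosine(u: np.ndarray) -> np.ndarray:
    """Smooth unimodal bump: 0.5 (1 + cos 2 pi u) on |u| <= 1/2, else 0."""
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) <= 0.5, 0.5 * (1.0 + np.cos(2 * np.pi * u)), 0.0)
    return out


def generate_strain(rng, rr: float, dys_level: float,
                    amplitudes: dict, pvc_time: float,
                    config: SimulationConfig,
                    psc_force: Optional[dict] = None,
                    walls=None) -> tuple[dict, dict]:
    """Per-wall strain series for one synthetic patient.

    Wall ``w`` gets s_w(t) = -A_w * phi((t - tau_w) / (width * RR)) plus
    noise, with tau_w = tau_frac * RR + RR * (D / 100) * z_w and z the
    standardized (mean 0, sample SD 1) offsets over the six walls.  Views
    in ``psc_force`` have the free-wall peak displaced beyond
    PVC + 1.5 frames (plus an exponential tail), guaranteeing a PSC call
    at zero noise.

    Returns (series by wall, realized tau by wall).
    """
    config.validate()
    if any(a <= 0 for a in amplitudes.values()):
        raise ValueError("config error: amplitudes must be > 0")
    psc_force = psc_force or {}
    n_phases = config.n_phases
    f = rr / n_phases
    times = np.arange(n_phases) * f

    z = rng.standard_normal(len(WALL_ORDER))
    while np.std(z, ddof=1) < 1e-9:
        z = rng.standard_normal(len(WALL_ORDER))
    z = (z - z.mean()) / np.std(z, ddof=1)
    tau = {w: config.tau_frac * rr + rr * (dys_level / 100.0) * z[i]
           for i, w in enumerate(WALL_ORDER)}

    for view, forced in psc_force.items():
        if forced:
            shift = pvc_time + 1.5 * f + rng.exponential(config.psc_shift_ms)
            for w in PSC_REPRESENTATIVE[view]:
                tau[w] = shift

    series = {}
    use_walls = list(WALL_ORDER) if walls is None else list(walls)
    for w in use_walls:
        t_w = float(np.clip(tau[w], 1.5 * f, rr - f))
        tau[w] = t_w
        vals = -amplitudes[w] * raised_cosine(
            (times - t_w) / (config.width_frac * rr))
        if config.noise_sd > 0:
            vals = vals + rng.normal(0.0, config.noise_sd, size=n_phases)
        vals[0] = 0.0
        series[w] = StrainSeries(
            view=w.view, wall=w, direction=direction_for_view(w.view),
            times=times.copy(), values=vals, rr_interval=rr,
            frame_duration=f)
    return series, {w: tau[w] for w in use_walls}


def generate_survival(dys_level, age, config: SimulationConfig, rng
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Proportional-hazards event times with administrative censoring.

    T_i is exponential with rate h0 * exp(beta_dys * D_i + beta_age *
    age_i); entry is uniform over the accrual window, so the censoring
    time is uniform on [horizon - accrual, horizon].  Returns follow-up
    months and event indicators.
    """
    config.validate()
    D = np.asarray(dys_level, dtype=float)
    age = np.asarray(age, dtype=float)
    rate = config.h0 * np.exp(config.beta_dys * D + config.beta_age * age)
    T = rng.exponential(1.0 / rate)
    C = config.horizon_months - rng.uniform(
        0.0, config.accrual_months, size=D.shape)
    followup = np.minimum(T, C)
    event = (T <= C).astype(int)
    return followup, event


def generate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a complete synthetic cohort: covariates, curves, outcomes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    hr = _trunc_normal(rng, config.hr_mean, config.hr_sd,
                       config.hr_min, config.hr_max, size=n)
    rr = 60000.0 / hr
    age = _trunc_normal(rng, config.age_mean, config.age_sd,
                        config.age_min, config.age_max, size=n)
    sex = np.where(rng.uniform(size=n) < config.female_fraction,
                   "female", "male")
    D = _trunc_normal(rng, config.dys_mean, config.dys_sd, low=0.0, size=n)
    followup, event = generate_survival(D, age, config, rng)

    patients = []
    strain_by_patient = {}
    latent_rows = []
    amp_mean = {View.RV3CH: config.amp_rv3ch, View.CH4: config.amp_4ch,
                View.SAX: config.amp_sax}
    psc_probs = {View.RV3CH: config.psc_prob_rv3ch,
                 View.CH4: config.psc_prob_4ch,
                 View.SAX: config.psc_prob_sax}
    sources = np.array(["RVOT", "RV3ch", "SAX"])

    for i in range(n):
        pid = f"P{i + 1:04d}"
        missing_rv3ch = rng.uniform() < config.rv3ch_missing_frac
        views = ({View.CH4, View.SAX} if missing_rv3ch
                 else {View.RV3CH, View.CH4, View.SAX})
        pvc = config.systole_frac * rr[i]
        pvc_source = str(rng.choice(sources, p=list(config.pvc_source_probs)))
        psc_force = {v: bool(rng.uniform() < psc_probs[v])
                     for v in views if psc_probs[v] is not None}
        amps = {w: _trunc_normal(rng, amp_mean[w.view], config.amp_sd,
                                 low=config.amp_min)
                for w in WALL_ORDER}
        wall_subset = [w for w in WALL_ORDER if w.view in views]
        series, tau = generate_strain(
            rng, rr[i], D[i], amps, pvc, config,
            psc_force=psc_force, walls=wall_subset)
        strain_by_patient[pid] = series

        mpap = _trunc_normal(rng, config.mpap_mean, config.mpap_sd, low=20.0)
        pawp = _trunc_normal(rng, config.pawp_mean, config.pawp_sd,
                             low=1.0, high=min(15.0, mpap - 2.0))
        co = _trunc_normal(rng, config.co_mean, config.co_sd, low=1.5)
        mrap = _trunc_normal(rng, config.mrap_mean, config.mrap_sd, low=0.0)
        days = float(np.round(rng.exponential(config.days_rhc_scale)))
        patients.append(PatientRecord(
            patient_id=pid,
            age=float(age[i]),
            sex=str(sex[i]),
            rr_interval=float(rr[i]),
            n_phases=config.n_phases,
            pvc_rvot_ms=float(pvc),
            pvc_source=pvc_source,
            available_views=frozenset(views),
            event=int(event[i]),
            followup_time=float(followup[i]),
            incident=int(rng.uniform() < config.incident_fraction),
            mpap=mpap, pawp=pawp, cardiac_output=co,
            pvr=compute_pvr(mpap, pawp, co), mrap=mrap,
            days_rhc_to_cmr=days,
            medication_change=int(rng.uniform() < config.med_change_prob),
            fibrosis_insertion=int(rng.uniform() < config.fibrosis_insertion_prob),
            fibrosis_septal=int(rng.uniform() < config.fibrosis_septal_prob),
            fibrosis_lateral=int(rng.uniform() < config.fibrosis_lateral_prob),
            rvef=_trunc_normal(rng, config.rvef_mean, config.rvef_sd,
                               low=5.0, high=75.0),
        ))
        row = {"patient_id": pid, "D": float(D[i]), "rr_ms": float(rr[i]),
               "pvc_ms": float(pvc), "missing_rv3ch": int(missing_rv3ch)}
        for v, flag in psc_force.items():
            row[f"psc_forced_{v.value}"] = int(flag)
        for w in wall_subset:
            row[f"tau_{w.value}"] = float(tau[w])
        latent_rows.append(row)

    cohort = CohortTable(patients, metadata={
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "schema_version": SCHEMA_VERSION,
        "synthetic": True,
    })
    return SimulatedCohort(cohort=cohort, strain=strain_by_patient,
                           latents=pd.DataFrame(latent_rows), config=config)
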