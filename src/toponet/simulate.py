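"""Synthetic vital-sign cohorts with controllable tachycardia events.

The generator exists so every other stage — onset labeling, feature
extraction, sampling, training, monitoring — is exercisable end-to-end
without access to any clinical database. Each patient gets per-minute
HR/RR/SpO2 streams as stationary AR(1) noise around channel baselines, plus
a static profile drawn from admission-statistics presets for an ICU-style
and a general-ward-style cohort.

Event patients additionally receive a *prodrome* — a linear pre-onset drift
(HR up, RR up, SpO2 down) with inflated HR noise over a configurable lead
window — followed by a sustained HR plateau that satisfies the >100 bpm /
>=30 min onset rule by construction. The prodrome is the recoverable signal
the classifier is supposed to learn; its lead and amplitudes are explicit so
tests can reason about which forecast ranges contain signal.

Ground truth is exact: to guarantee the labeled onset equals the injected
minute on every seed, event patients' pre-onset heart rate is capped at
100 bpm (never strictly above threshold) and the plateau is floored just
above it. Event-free patients are uncapped; at baseline 75 bpm (sd 8), a
30-minute run above 100 bpm by noise alone is vanishingly unlikely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vitals import CARE_UNITS, PatientRecord, StaticProfile, VitalChannel


@dataclass(frozen=True)
class StaticPreset:
    """Categorical probabilities and an age distribution for one cohort."""

    female_p: float
    admission_probs: tuple[float, float, float]  # elective, emergency, urgent
    unit_probs: tuple[float, ...] | None         # per CARE_UNITS; None = ward
    cvd_p: float
    age_median: float
    age_sigma: float  # normal spread, IQR / 1.349

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.admission_probs), 1.0):
            raise ValueError("admission probabilities must sum to 1")
        if self.unit_probs is not None and not np.isclose(sum(self.unit_probs), 1.0):
            raise ValueError("care-unit probabilities must sum to 1")


ICU_STATIC = StaticPreset(
    female_p=0.572,
    admission_probs=(0.172, 0.798, 0.030),
    unit_probs=(0.209, 0.196, 0.263, 0.232, 0.100),
    cvd_p=0.866,
    age_median=66.15,
    age_sigma=(77.78 - 53.97) / 1.349,
)

WARD_STATIC = StaticPreset(
    female_p=0.405,
    admission_probs=(0.876, 0.124, 0.0),
    unit_probs=None,
    cvd_p=0.903,
    age_median=61.0,
    age_sigma=(67.5 - 53.0) / 1.349,
)


@dataclass(frozen=True)
class ProdromeSpec:
    """Pre-onset drift geometry and the post-onset event plateau."""

    lead: int = 360               # minutes before onset the drift begins
    hr_drift: float = 18.0        # bpm rise over the lead (linear ramp)
    rr_drift: float = 6.0         # breaths/min rise
    spo2_dip: float = 3.0         # % fall
    variance_inflation: float = 1.5  # multiplier on HR noise sd in the prodrome
    plateau_bpm: float = 112.0    # event heart-rate level
    plateau_minutes: int = 45     # >= 30 so the (>100, 30 min) rule fires

    def __post_init__(self) -> None:
        if self.lead <= 0:
            raise ValueError("lead must be positive")
        if not (self.plateau_bpm > 100 and self.plateau_minutes >= 30):
            raise ValueError("plateau must satisfy the >100 bpm / >=30 min rule")


#: drift-free control prodrome: events still occur but carry no early signal
NULL_PRODROME = ProdromeSpec(hr_drift=0.0, rr_drift=0.0, spo2_dip=0.0,
                             variance_inflation=1.0)


@dataclass(frozen=True)
class CohortParams:
    n_patients: int = 100
    prevalence: float = 0.5
    span_min: int = 900           # monitoring minutes, inclusive
    span_max: int = 1440
    baselines: tuple[float, float, float] = (75.0, 16.0, 97.0)   # hr, rr, spo2
    noise_sd: tuple[float, float, float] = (8.0, 3.0, 1.5)
    ar_coef: tuple[float, float, float] = (0.9, 0.85, 0.9)
    static: StaticPreset = ICU_STATIC
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must be in [0, 1]")
        if any(not 0 <= a < 1 for a in self.ar_coef):
            raise ValueError("AR coefficients must be in [0, 1)")


def ward_params(**overrides) -> CohortParams:
    """General-ward preset: shorter stays, ward admission statistics."""
    base = dict(span_min=480, span_max=840, static=WARD_STATIC)
    base.update(overrides)
    return CohortParams(**base)


#: ward prodrome with a shorter lead so events fit inside shorter stays
WARD_PRODROME = ProdromeSpec(lead=240)


def _ar1(rng, n: int, mu: float, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) around mu with marginal standard deviation sd."""
    if sd == 0:
        return np.full(n, mu)
    innov_sd = sd * np.sqrt(1 - phi * phi)
    x = np.empty(n)
    x[0] = mu + rng.normal(0, sd)
    eps = rng.normal(0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = mu + phi * (x[t - 1] - mu) + eps[t - 1]
    return x


def sample_static_profile(preset: StaticPreset, rng) -> StaticProfile:
    """One categorical/age draw from a cohort preset."""
    age = float(rng.normal(preset.age_median, preset.age_sigma))
    while age <= 18:
        age = float(rng.normal(preset.age_median, preset.age_sigma))
    gender = "female" if rng.random() < preset.female_p else "male"
    admission = ("elective", "emergency", "urgent")[
        int(rng.choice(3, p=preset.admission_probs))
    ]
    if preset.unit_probs is None:
        unit = None
    else:
        unit = CARE_UNITS[int(rng.choice(len(CARE_UNITS), p=preset.unit_probs))]
    cvd = bool(rng.random() < preset.cvd_p)
    return StaticProfile(age, gender, admission, unit, cvd)


def generate_patient(
    params: CohortParams,
    prodrome: ProdromeSpec | None,
    seed,
    patient_id: str = "P0",
) -> tuple[PatientRecord, int | None]:
    """One record plus its ground-truth onset minute (None if event-free).

    ``seed`` may be an int or a numpy SeedSequence (cohort spawning).
    """
    rng = np.random.default_rng(seed)
    span = int(rng.integers(params.span_min, params.span_max + 1))
    (hr_mu, rr_mu, sp_mu) = params.baselines
    (hr_sd, rr_sd, sp_sd) = params.noise_sd
    (hr_phi, rr_phi, sp_phi) = params.ar_coef

    hr = _ar1(rng, span, hr_mu, hr_sd, hr_phi)
    rr = _ar1(rng, span, rr_mu, rr_sd, rr_phi)
    spo2 = _ar1(rng, span, sp_mu, sp_sd, sp_phi)
    onset: int | None = None

    if prodrome is not None:
        earliest = prodrome.lead + 120  # leave a full observing window pre-drift
        latest = span - prodrome.plateau_minutes
        if latest < earliest:
            raise ValueError(
                f"span {span} too short for prodrome lead {prodrome.lead} "
                f"+ observing window + plateau"
            )
        onset = int(rng.integers(earliest, latest + 1))
        ramp = np.linspace(0, 1, prodrome.lead, endpoint=False)
        pro = slice(onset - prodrome.lead, onset)
        hr[pro] = hr_mu + ramp * prodrome.hr_drift + (
            hr[pro] - hr_mu
        ) * prodrome.variance_inflation
        rr[pro] += ramp * prodrome.rr_drift
        spo2[pro] -= ramp * prodrome.spo2_dip
        # event plateau: strictly above 100 bpm for >= plateau_minutes
        plat = slice(onset, onset + prodrome.plateau_minutes)
        hr[plat] = np.maximum(prodrome.plateau_bpm + (hr[plat] - hr_mu), 101.0)
        # exact ground truth: pre-onset HR never strictly exceeds 100 bpm
        hr[: onset] = np.minimum(hr[: onset], 100.0)

    hr = np.clip(hr, 20.0, 250.0)
    rr = np.clip(rr, 4.0, 60.0)
    spo2 = np.clip(spo2, 60.0, 100.0)

    profile = sample_static_profile(params.static, rng)
    record = PatientRecord(
        patient_id,
        {
            "hr": VitalChannel("hr", hr),
            "rr": VitalChannel("rr", rr),
            "spo2": VitalChannel("spo2", spo2),
        },
        profile,
    )
    return record, onset


def generate_cohort(
    params: CohortParams,
    prodrome: ProdromeSpec | None = None,
    seed: int | None = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Seeded cohort with exactly ``round(n * prevalence)`` event patients.

    Returns the records and a truth table (patient_id, has_event,
    onset_minute, prodrome_start, span). All per-patient randomness derives
    from one root seed, so cohorts are reproducible and any patient can be
    regenerated alone.
    """
    if params.n_patients < 1:
        raise ValueError("need at least one patient")
    seed = params.seed if seed is None else seed
    prodrome = prodrome or ProdromeSpec()
    root = np.random.SeedSequence(seed)
    alloc_rng = np.random.default_rng(root.spawn(1)[0])
    n_events = int(round(params.n_patients * params.prevalence))
    flags = np.zeros(params.n_patients, dtype=bool)
    flags[alloc_rng.choice(params.n_patients, size=n_events, replace=False)] = True

    children = root.spawn(params.n_patients + 1)[1:]
    records, rows = [], []
    for i, (flag, child) in enumerate(zip(flags, children)):
        pid = f"P{i:04d}"
        rec, onset = generate_patient(
            params, prodrome if flag else None, child, patient_id=pid
        )
        records.append(rec)
        rows.append(
            {
                "patient_id": pid,
                "has_event": bool(flag),
                "onset_minute": onset if onset is not None else pd.NA,
                "prodrome_start": (onset - prodrome.lead) if onset is not None else pd.NA,
                "span": rec.n_minutes,
            }
        )
    return records, pd.DataFrame(rows)


def cohort_to_frames(records: list[PatientRecord]):
    """(vitals dict for write_vitals_csv, profiles dict for write_static_csv)."""
    vitals = {
        r.patient_id: {c: r.channels[c].values for c in ("hr", "rr", "spo2")}
        for r in records
    }
    profiles = {r.patient_id: r.profile for r in records}
    return vitals, profiles
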