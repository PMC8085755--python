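"""Vital-sign data model and preprocessing.

Continuous monitors report heart rate (bpm), respiratory rate (breaths/min)
and SpO2 (%) at up to per-second resolution. Modelling happens on a shared
per-minute grid: per-second samples are averaged within each minute, minutes
dominated by null/zero readings are marked missing, and gaps are filled
causally (last observation carried forward) so that no future information
leaks into a window.

Minute indexing is 0-based from the start of the record; all windows
elsewhere in the package are half-open ``[end - width, end)`` in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHANNELS = ("hr", "rr", "spo2")

#: physiological plausibility bounds per channel (exclusive low, inclusive high)
CHANNEL_BOUNDS = {"hr": (0.0, 300.0), "rr": (0.0, 80.0), "spo2": (0.0, 100.0)}

#: a minute whose fraction of null/zero per-second samples exceeds this is missing
NULL_FRACTION_THRESHOLD = 0.30

ADMISSION_TYPES = ("elective", "emergency", "urgent")
CARE_UNITS = (
    "coronary",
    "cardiac-surgery-recovery",
    "medical-ICU",
    "surgical-ICU",
    "trauma-surgical-ICU",
)
GENDERS = ("female", "male")


@dataclass(frozen=True)
class StaticProfile:
    """Admission-time patient attributes fused with the vital-sign features.

    ``first_care_unit`` may be ``None`` for general-ward patients, who are
    never admitted to an ICU bed.
    """

    age: float
    gender: str
    admission_type: str
    first_care_unit: str | None
    cvd_history: bool

    def __post_init__(self) -> None:
        if not self.age > 18:
            raise ValueError(f"age must exceed 18 years, got {self.age}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.admission_type not in ADMISSION_TYPES:
            raise ValueError(f"unknown admission type {self.admission_type!r}")
        if self.first_care_unit is not None and self.first_care_unit not in CARE_UNITS:
            raise ValueError(f"unknown first care unit {self.first_care_unit!r}")


@dataclass
class VitalChannel:
    """One per-minute vital-sign series; NaN marks a missing minute."""

    name: str
    values: np.ndarray
    start_minute: int = 0

    def __post_init__(self) -> None:
        if self.name not in CHANNELS:
            raise ValueError(f"unknown channel {self.name!r}")
        self.values = np.asarray(self.values, dtype=float)
        lo, hi = CHANNEL_BOUNDS[self.name]
        observed = self.values[~np.isnan(self.values)]
        if observed.size and ((observed <= lo) | (observed > hi)).any():
            raise ValueError(
                f"{self.name} values outside ({lo}, {hi}]: "
                f"min={observed.min():g}, max={observed.max():g}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class PatientRecord:
    """Aligned per-minute HR/RR/SpO2 streams plus the static profile."""

    patient_id: str
    channels: dict[str, VitalChannel]
    profile: StaticProfile = field(repr=False)

    def __post_init__(self) -> None:
        if set(self.channels) != set(CHANNELS):
            raise ValueError(f"record needs channels {CHANNELS}, got {tuple(self.channels)}")
        lengths = {len(ch) for ch in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError(f"channel lengths differ: {lengths}")

    @property
    def n_minutes(self) -> int:
        return len(self.channels["hr"])

    def channel_matrix(self) -> np.ndarray:
        """(n_minutes, 3) array in (hr, rr, spo2) column order."""
        return np.column_stack([self.channels[c].values for c in CHANNELS])


def downsample_to_minute(
    per_second: np.ndarray | list,
    samples_per_minute: int = 60,
    null_threshold: float = NULL_FRACTION_THRESHOLD,
) -> np.ndarray:
    """Average per-second samples to a per-minute series.

    Null (NaN) and zero readings are sensor dropouts, not physiology; they are
    excluded from the minute mean. A minute in which the dropout fraction
    exceeds ``null_threshold`` carries no trustworthy signal and is emitted as
    NaN for the downstream forward fill.

    Parameters
    ----------
    per_second
        Flat array of samples; every ``samples_per_minute`` consecutive values
        form one minute. A trailing partial minute is allowed.
    """
    x = np.asarray(per_second, dtype=float)
    if x.size == 0:
        raise ValueError("empty per-second input")
    n_minutes = int(np.ceil(x.size / samples_per_minute))
    out = np.empty(n_minutes)
    for m in range(n_minutes):
        group = x[m * samples_per_minute : (m + 1) * samples_per_minute]
        invalid = np.isnan(group) | (group == 0)
        if invalid.mean() > null_threshold:
            out[m] = np.nan
        else:
            out[m] = group[~invalid].mean()
    return out


def fill_missing(series: np.ndarray | list) -> np.ndarray:
    """Forward-fill missing minutes; trim leading minutes with no predecessor.

    Filling is strictly causal (last observation carried forward), as required
    for real-time scoring. Idempotent.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    observed = ~np.isnan(x)
    if not observed.any():
        raise ValueError("all-missing series cannot be filled")
    first = int(np.argmax(observed))
    x = x[first:]
    # vectorised LOCF: index of most recent observed position at or before i
    idx = np.where(~np.isnan(x), np.arange(x.size), 0)
    np.maximum.accumulate(idx, out=idx)
    return x[idx]


def preprocess_record(
    patient_id: str,
    raw: dict[str, np.ndarray],
    profile: StaticProfile,
) -> PatientRecord:
    """Build a complete PatientRecord from per-minute series with gaps.

    Channels are forward-filled individually, then truncated to a common span:
    the start is the latest post-trim start across channels and the end the
    shortest channel end, so the three series share one minute grid.
    """
    filled = {}
    trims = {}
    for name in CHANNELS:
        x = np.asarray(raw[name], dtype=float)
        observed = ~np.isnan(x)
        if not observed.any():
            raise ValueError(f"channel {name} of {patient_id} is entirely missing")
        trims[name] = int(np.argmax(observed))
        filled[name] = fill_missing(x)
    # align: channel i now starts at original minute trims[i]
    start = max(trims.values())
    end = min(trims[n] + len(filled[n]) for n in CHANNELS)
    if end <= start:
        raise ValueError(f"channels of {patient_id} have no common span")
    channels = {
        n: VitalChannel(n, filled[n][start - trims[n] : end - trims[n]], start_minute=start)
        for n in CHANNELS
    }
    return PatientRecord(patient_id, channels, profile)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

def read_vitals_csv(path) -> dict[str, dict[str, np.ndarray]]:
    """Read a long-format vitals CSV (patient_id, minute, hr, rr, spo2).

    Empty cells are missing. Returns per-patient dense per-minute arrays
    spanning minute 0 to the last recorded minute.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "minute", "hr", "rr", "spo2"}
    if not required.issubset(df.columns):
        raise ValueError(f"vitals CSV needs columns {sorted(required)}")
    out: dict[str, dict[str, np.ndarray]] = {}
    for pid, grp in df.groupby("patient_id", sort=True):
        n = int(grp["minute"].max()) + 1
        dense = {c: np.full(n, np.nan) for c in CHANNELS}
        idx = grp["minute"].to_numpy(dtype=int)
        for c in CHANNELS:
            dense[c][idx] = grp[c].to_numpy(dtype=float)
        out[str(pid)] = dense
    return out


def write_vitals_csv(path, records: dict[str, dict[str, np.ndarray]]) -> None:
    frames = []
    for pid in sorted(records):
        series = records[pid]
        n = len(series["hr"])
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "minute": np.arange(n),
                    "hr": series["hr"],
                    "rr": series["rr"],
                    "spo2": series["spo2"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")


def read_static_csv(path) -> dict[str, StaticProfile]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    profiles = {}
    for row in df.itertuples(index=False):
        unit = getattr(row, "first_care_unit", None)
        if unit is not None and (pd.isna(unit) or unit in ("", "none")):
            unit = None
        profiles[str(row.patient_id)] = StaticProfile(
            age=float(row.age),
            gender=str(row.gender),
            admission_type=str(row.admission_type),
            first_care_unit=unit,
            cvd_history=bool(row.cvd_history),
        )
    return profiles


def write_static_csv(path, profiles: dict[str, StaticProfile]) -> None:
    rows = [
        {
            "patient_id": pid,
            "age": p.age,
            "gender": p.gender,
            "admission_type": p.admission_type,
            "first_care_unit": p.first_care_unit if p.first_care_unit else "none",
            "cvd_history": int(p.cvd_history),
        }
        for pid, p in sorted(profiles.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.2f")
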