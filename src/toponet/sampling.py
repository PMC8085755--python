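"""Labeled-sample construction from monitored records.

Negatives come only from records with no detected tachycardia: one observing
window every 60 minutes across the whole record. Positives come from records
with an onset: the observing window ending ``forecast_range`` before onset,
augmented by re-extracting windows shifted 5 minutes earlier (target
replication) to enlarge the minority class. Negatives are then randomly
subsampled to the positive count, and the set is split 80/20 at the patient
level so no patient's windows leak between train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .features import WindowGeometry, extract_sequence
from .model import encode_static
from .onset import OnsetEvent, detect_onset
from .vitals import PatientRecord


@dataclass(frozen=True)
class SamplingConfig:
    observing_window: int = 120     # minutes
    neg_stride: int = 60            # minutes between negative window ends
    forecast_range: int = 2         # hours between window end and onset
    replication_step: int = 5       # minutes between replicated positive windows
    replication_count: int = 4      # extra positive windows per onset
    min_monitoring: int = 840       # record-inclusion floor (ICU-style, minutes)
    min_age: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forecast_range < 0 or self.replication_count < 0:
            raise ValueError("forecast_range and replication_count must be >= 0")

    @property
    def forecast_minutes(self) -> int:
        return self.forecast_range * 60


WARD_MIN_MONITORING = 240  # general-ward inclusion floor, minutes


@dataclass
class LabeledSample:
    features: np.ndarray          # (n_steps, n_features)
    static_vector: np.ndarray     # (11,)
    label: int
    patient_id: str
    window_end: int
    forecast_range: int           # hours

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


def negative_window_ends(record_length: int, config: SamplingConfig) -> list[int]:
    """Window ends for a tachycardia-free record: 120, 180, ... <= length."""
    if record_length < config.observing_window:
        return []
    return list(range(config.observing_window, record_length + 1, config.neg_stride))


def positive_window_ends(
    onset_minute: int, record_length: int, config: SamplingConfig
) -> list[int]:
    """Base window end at onset - forecast, plus replicated earlier ends."""
    base = onset_minute - config.forecast_minutes
    ends = []
    for r in range(config.replication_count + 1):
        end = base - r * config.replication_step
        if config.observing_window <= end <= record_length:
            ends.append(end)
    return ends


def _make_sample(record: PatientRecord, end: int, label: int,
                 config: SamplingConfig, geometry: WindowGeometry) -> LabeledSample:
    return LabeledSample(
        features=extract_sequence(record, end, geometry),
        static_vector=encode_static(record.profile),
        label=label,
        patient_id=record.patient_id,
        window_end=end,
        forecast_range=config.forecast_range,
    )


def extract_negatives(
    record: PatientRecord,
    config: SamplingConfig,
    geometry: WindowGeometry | None = None,
) -> list[LabeledSample]:
    """All strided negative windows of a record with no detected onset."""
    if detect_onset(record.channels["hr"].values) is not None:
        raise ValueError(f"record {record.patient_id} has a tachycardia onset")
    geometry = geometry or WindowGeometry(observing_window=config.observing_window)
    return [
        _make_sample(record, end, 0, config, geometry)
        for end in negative_window_ends(record.n_minutes, config)
    ]


def extract_positives(
    record: PatientRecord,
    onset: OnsetEvent,
    config: SamplingConfig,
    geometry: WindowGeometry | None = None,
) -> list[LabeledSample]:
    """Forecast-offset windows before the onset, with 5-minute replication."""
    geometry = geometry or WindowGeometry(observing_window=config.observing_window)
    return [
        _make_sample(record, end, 1, config, geometry)
        for end in positive_window_ends(onset.onset_minute, record.n_minutes, config)
    ]


def build_samples(
    records: list[PatientRecord],
    config: SamplingConfig,
    geometry: WindowGeometry | None = None,
) -> list[LabeledSample]:
    """Apply inclusion filters and extract positives/negatives per record.

    Records shorter than ``min_monitoring`` or from patients aged at or below
    ``min_age`` are excluded. Records with an onset contribute only
    positives; onset-free records only negatives.
    """
    samples: list[LabeledSample] = []
    for rec in records:
        if rec.n_minutes < config.min_monitoring or rec.profile.age <= config.min_age:
            continue
        onset = detect_onset(rec.channels["hr"].values)
        if onset is None:
            samples.extend(extract_negatives(rec, config, geometry))
        else:
            samples.extend(extract_positives(rec, onset, config, geometry))
    return samples


def balance_and_split(
    samples: list[LabeledSample],
    seed: int,
    train_fraction: float = 0.8,
) -> tuple[list[LabeledSample], list[LabeledSample]]:
    """Subsample negatives to the positive count; split by patient 80/20.

    Both steps are seeded and reproducible; all windows of one patient land
    on the same side of the split.
    """
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos or not neg:
        raise ValueError("both classes must be present to balance and split")
    rng = np.random.default_rng(seed)
    if len(neg) > len(pos):
        keep = rng.choice(len(neg), size=len(pos), replace=False)
        neg = [neg[i] for i in sorted(keep)]
    balanced = pos + neg
    patients = sorted({s.patient_id for s in balanced})
    rng.shuffle(patients)
    n_train = int(round(train_fraction * len(patients)))
    train_ids = set(patients[:n_train])
    train = [s for s in balanced if s.patient_id in train_ids]
    test = [s for s in balanced if s.patient_id not in train_ids]
    return train, test


def with_forecast_range(config: SamplingConfig, hours: int) -> SamplingConfig:
    return replace(config, forecast_range=hours)
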