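"""Tachycardia onset labeling from per-minute heart rate.

Onset is rule-based: a sustained run of minutes strictly above a bpm
threshold. The default criteria — (>100 bpm for >=30 min), (>130 for >=20),
(>150 for >=5) — grade severity against duration: the faster the rate, the
shorter the exposure needed to call an event. The earliest minute at which
any criterion is met is the onset; ties between criteria whose qualifying
runs start at the same minute go to the higher threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TachycardiaCriterion:
    hr_threshold: float  # bpm, exceedance is strict (>)
    min_duration: int    # minutes, run length >= min_duration qualifies

    def __post_init__(self) -> None:
        if self.hr_threshold <= 0 or self.min_duration < 1:
            raise ValueError("criterion needs positive threshold and duration")


DEFAULT_CRITERIA = (
    TachycardiaCriterion(100, 30),
    TachycardiaCriterion(130, 20),
    TachycardiaCriterion(150, 5),
)


@dataclass(frozen=True)
class OnsetEvent:
    onset_minute: int
    criterion: TachycardiaCriterion
    run_length: int  # length of the maximal run that qualified


def _runs_above(hr: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of minutes with hr strictly above threshold, as (start, length)."""
    above = hr > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(hr))
    return [(s, e - s) for s, e in zip(starts, ends)]


def detect_onset(
    hr: np.ndarray | list,
    criteria: tuple[TachycardiaCriterion, ...] = DEFAULT_CRITERIA,
) -> OnsetEvent | None:
    """First tachycardia onset in a complete per-minute heart-rate series.

    Returns the event whose qualifying run starts earliest, or None when no
    run satisfies any criterion. The series must be gap-free (preprocessed).
    """
    x = np.asarray(hr, dtype=float)
    if x.size == 0:
        raise ValueError("empty heart-rate series")
    if np.isnan(x).any():
        raise ValueError("heart-rate series contains missing values; preprocess first")
    best: OnsetEvent | None = None
    for crit in criteria:
        for start, length in _runs_above(x, crit.hr_threshold):
            if length >= crit.min_duration:
                cand = OnsetEvent(start, crit, length)
                if (
                    best is None
                    or cand.onset_minute < best.onset_minute
                    or (
                        cand.onset_minute == best.onset_minute
                        and cand.criterion.hr_threshold > best.criterion.hr_threshold
                    )
                ):
                    best = cand
                break  # runs are in time order; later runs cannot start earlier
    return best


def detect_all_onsets(
    hr: np.ndarray | list,
    criteria: tuple[TachycardiaCriterion, ...] = DEFAULT_CRITERIA,
) -> list[OnsetEvent]:
    """All qualifying-run starts, time-ordered (simulator bookkeeping).

    Only the first event labels a record for modelling; recurrence is not
    modelled but the simulator uses this to audit injected events.
    """
    x = np.asarray(hr, dtype=float)
    if x.size == 0:
        raise ValueError("empty heart-rate series")
    events: dict[int, OnsetEvent] = {}
    for crit in criteria:
        for start, length in _runs_above(x, crit.hr_threshold):
            if length >= crit.min_duration:
                prev = events.get(start)
                if prev is None or crit.hr_threshold > prev.criterion.hr_threshold:
                    events[start] = OnsetEvent(start, crit, length)
    return [events[k] for k in sorted(events)]


def label_cohort(records) -> pd.DataFrame:
    """Onset table for a list of PatientRecords (one row per patient)."""
    rows = []
    for rec in records:
        ev = detect_onset(rec.channels["hr"].values)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "onset_minute": ev.onset_minute if ev else pd.NA,
                "threshold": ev.criterion.hr_threshold if ev else pd.NA,
                "duration": ev.criterion.min_duration if ev else pd.NA,
                "run_length": ev.run_length if ev else pd.NA,
            }
        )
    return pd.DataFrame(rows)
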