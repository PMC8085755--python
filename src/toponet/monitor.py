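"""Real-time risk streaming and persistence-gated alarms.

A fitted model is replayed over a monitoring record: every 5 minutes (first
evaluation once 120 minutes of history exist) the trailing observing window
is featurised and scored, strictly causally. An alarm is raised at the k-th
consecutive evaluation whose score strictly exceeds the threshold (default
0.40 with persistence 1). Lead time is the gap between the alarm and the
subsequent onset; a missed or late alarm is a first-class outcome, not an
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import WindowGeometry, extract_sequence
from .model import TachycardiaOnsetResults, encode_static
from .vitals import PatientRecord


@dataclass(frozen=True)
class MonitorConfig:
    evaluation_step: int = 5   # minutes between risk evaluations
    threshold: float = 0.40    # alarm when score strictly exceeds this
    persistence: int = 1       # consecutive exceedances required

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


@dataclass
class AlarmResult:
    alarm_minute: int | None
    scores: np.ndarray                 # (n_evaluations, 2): minute, score
    lead_time: int | None = None
    late: bool = False
    missed: bool = False


def evaluation_minutes(record_length: int, config: MonitorConfig,
                       geometry: WindowGeometry | None = None) -> list[int]:
    geometry = geometry or WindowGeometry()
    if record_length < geometry.observing_window:
        return []
    return list(range(geometry.observing_window, record_length + 1,
                      config.evaluation_step))


def stream_scores(
    record: PatientRecord,
    results: TachycardiaOnsetResults,
    config: MonitorConfig | None = None,
    geometry: WindowGeometry | None = None,
    until_minute: int | None = None,
) -> np.ndarray:
    """(minute, score) pairs for every evaluation step of the record.

    Each score uses only the trailing observing window ending at that
    minute; truncating the record after minute t cannot change any score at
    or before t.
    """
    config = config or MonitorConfig()
    geometry = geometry or WindowGeometry()
    length = record.n_minutes if until_minute is None else min(until_minute,
                                                               record.n_minutes)
    minutes = evaluation_minutes(length, config, geometry)
    if not minutes:
        return np.empty((0, 2))
    static = encode_static(record.profile)
    X_seq = np.stack([extract_sequence(record, t, geometry) for t in minutes])
    X_static = np.repeat(static[None, :], len(minutes), axis=0)
    scores = results.predict_arrays(X_seq, X_static)
    return np.column_stack([minutes, scores])


def raise_alarm(scores: np.ndarray, config: MonitorConfig | None = None) -> AlarmResult:
    """Persistence-gated alarm over a time-ordered (minute, score) series.

    The alarm minute is the evaluation at which the run of consecutive
    exceedances first reaches length ``persistence``; a sub-threshold
    evaluation resets the run.
    """
    config = config or MonitorConfig()
    scores = np.asarray(scores, dtype=float).reshape(-1, 2)
    run = 0
    for minute, score in scores:
        run = run + 1 if score > config.threshold else 0
        if run >= config.persistence:
            return AlarmResult(int(minute), scores)
    return AlarmResult(None, scores, missed=True)


def lead_time(alarm_minute: int | None, onset_minute: int | None
              ) -> tuple[int | None, bool]:
    """(minutes of warning, late_flag). Missed alarms return (None, False)."""
    if alarm_minute is None or onset_minute is None:
        return None, False
    if alarm_minute > onset_minute:
        return 0, True
    return onset_minute - alarm_minute, False


def monitor_record(
    record: PatientRecord,
    results: TachycardiaOnsetResults,
    onset_minute: int | None = None,
    config: MonitorConfig | None = None,
    geometry: WindowGeometry | None = None,
) -> AlarmResult:
    """Stream, alarm, and attach the lead time against a known onset."""
    config = config or MonitorConfig()
    scores = stream_scores(record, results, config, geometry,
                           until_minute=onset_minute)
    result = raise_alarm(scores, config)
    result.lead_time, result.late = lead_time(result.alarm_minute, onset_minute)
    return result


def plot_risk(record: PatientRecord, scores: np.ndarray,
              config: MonitorConfig | None = None,
              onset_minute: int | None = None, path=None):
    """Two-panel figure: heart rate on top, streamed risk below."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    config = config or MonitorConfig()
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(9, 5))
    hr = record.channels["hr"].values
    ax1.plot(np.arange(hr.size), hr, lw=0.8, color="tab:red")
    ax1.set_ylabel("heart rate (bpm)")
    ax2.plot(scores[:, 0], scores[:, 1], lw=1.2, color="tab:blue")
    ax2.axhline(config.threshold, ls="--", color="gray",
                label=f"threshold {config.threshold:.2f}")
    if onset_minute is not None:
        for ax in (ax1, ax2):
            ax.axvline(onset_minute, ls=":", color="black")
    ax2.set_xlabel("minutes from record start")
    ax2.set_ylabel("onset risk")
    ax2.set_ylim(0, 1)
    ax2.legend(loc="upper left", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
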