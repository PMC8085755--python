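"""Windowed statistical features over vital-sign streams.

One prediction sample summarises a 2-hour observing window of per-minute
HR/RR/SpO2. The window is sliced into 20-minute sub-windows with a 5-minute
stride — (120-20)/5 + 1 = 21 slices — and each slice is reduced to a fixed
21-value feature vector, so a sample is a 21x21 matrix ordered in time.

Three of the statistics are worth defining precisely (the rest are ordinary
moments, quantiles and a least-squares slope):

* absolute energy: ``sum(x_i^2)`` — overall signal magnitude;
* lag-l autocorrelation:
  ``R(l) = sum_{i<=n-l} (x_i - mu)(x_{i+l} - mu) / ((n - l) sigma^2)``
  with population variance ``sigma^2`` (0 by convention for a constant
  series) — periodicity/persistence at delay ``l``;
* c3 nonlinearity: ``mean(x_{i+2 lag} x_{i+lag} x_i)`` — a third-order
  moment sensitive to time-irreversibility that second-order statistics miss.

The single cross-channel feature, ``all_autocorrelation``, uses lag 40,
which exceeds a 20-sample sub-window; it is therefore computed once per
observing window (per channel over the full 120 minutes, then averaged over
the three channels) and replicated at every time step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vitals import CHANNELS, PatientRecord


@dataclass(frozen=True)
class WindowGeometry:
    """Observing-window slicing; defaults give 21 sub-windows of 20 minutes."""

    observing_window: int = 120  # minutes of history per sample
    sub_window: int = 20         # minutes per feature slice
    step: int = 5                # slice stride, minutes
    autocorr_lag: int = 40       # lag for the cross-channel autocorrelation

    def __post_init__(self) -> None:
        if (self.observing_window - self.sub_window) % self.step:
            raise ValueError("step must tile the observing window")
        if not 1 <= self.autocorr_lag < self.observing_window:
            raise ValueError("autocorrelation lag must be inside the observing window")

    @property
    def n_steps(self) -> int:
        return (self.observing_window - self.sub_window) // self.step + 1


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def abs_energy(x) -> float:
    """Sum of squared samples."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.dot(x, x))


def autocorrelation(x, lag: int) -> float:
    """Lag-``lag`` autocorrelation normalised by the population variance.

    Returns 0 for a constant series (zero variance), where the coefficient
    is undefined; a flat signal carries no similarity structure to measure.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 1 <= lag < n:
        raise ValueError(f"lag must satisfy 1 <= lag < n, got lag={lag}, n={n}")
    mu = x.mean()
    sigma2 = x.var()  # population estimator
    if sigma2 == 0:
        return 0.0
    d = x - mu
    return float(np.dot(d[:-lag], d[lag:]) / ((n - lag) * sigma2))


def c3(x, lag: int) -> float:
    """Third-order nonlinearity: mean of ``x[i+2*lag] * x[i+lag] * x[i]``."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * lag:
        raise ValueError(f"need n > 2*lag, got n={n}, lag={lag}")
    return float(np.mean(x[2 * lag :] * x[lag : n - lag] * x[: n - 2 * lag]))


def slope(x) -> float:
    """Least-squares linear trend against the sample index (units per minute)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("slope needs at least 2 samples")
    t = np.arange(n, dtype=float)
    t -= t.mean()
    return float(np.dot(t, x - x.mean()) / np.dot(t, t))


# ---------------------------------------------------------------------------
# Feature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    name: str
    channel: str          # hr / rr / spo2 / all
    function: str
    params: tuple = ()


def default_registry() -> list[FeatureSpec]:
    """The 21-feature registry: 10 HR + 5 RR + 5 SpO2 + 1 cross-channel.

    Order is part of the model contract; do not reorder. ``hr_c2`` is the c3
    statistic at lag 2 (the name keys the lag, not a different functional).
    """
    return [
        FeatureSpec("hr_mean", "hr", "mean"),
        FeatureSpec("hr_std", "hr", "std"),
        FeatureSpec("hr_sum", "hr", "sum"),
        FeatureSpec("hr_slope", "hr", "slope"),
        FeatureSpec("hr_abs_energy", "hr", "abs_energy"),
        FeatureSpec("hr_c2", "hr", "c3", (2,)),
        FeatureSpec("hr_c3", "hr", "c3", (3,)),
        FeatureSpec("hr_quantiles_01", "hr", "quantile", (0.1,)),
        FeatureSpec("hr_quantiles_03", "hr", "quantile", (0.3,)),
        FeatureSpec("hr_quantiles_07", "hr", "quantile", (0.7,)),
        FeatureSpec("resp_mean", "rr", "mean"),
        FeatureSpec("resp_std", "rr", "std"),
        FeatureSpec("resp_slope", "rr", "slope"),
        FeatureSpec("resp_abs_energy", "rr", "abs_energy"),
        FeatureSpec("resp_c3", "rr", "c3", (3,)),
        FeatureSpec("spo2_mean", "spo2", "mean"),
        FeatureSpec("spo2_std", "spo2", "std"),
        FeatureSpec("spo2_slope", "spo2", "slope"),
        FeatureSpec("spo2_c3", "spo2", "c3", (3,)),
        FeatureSpec("spo2_abs_energy", "spo2", "abs_energy"),
        FeatureSpec("all_autocorrelation", "all", "autocorr_agg", (40,)),
    ]


FEATURE_NAMES = tuple(s.name for s in default_registry())


def _apply(func: str, w: np.ndarray, params: tuple) -> np.ndarray:
    """Evaluate one per-sub-window statistic on a (n_windows, width) matrix."""
    if func == "mean":
        return w.mean(axis=1)
    if func == "std":
        return w.std(axis=1, ddof=1)  # sample SD
    if func == "sum":
        return w.sum(axis=1)
    if func == "slope":
        n = w.shape[1]
        t = np.arange(n, dtype=float)
        t -= t.mean()
        return (w - w.mean(axis=1, keepdims=True)) @ t / np.dot(t, t)
    if func == "abs_energy":
        return (w * w).sum(axis=1)
    if func == "c3":
        (lag,) = params
        n = w.shape[1]
        if n <= 2 * lag:
            raise ValueError(f"sub-window too short for c3 lag {lag}")
        return (w[:, 2 * lag :] * w[:, lag : n - lag] * w[:, : n - 2 * lag]).mean(axis=1)
    if func == "quantile":
        (q,) = params
        return np.quantile(w, q, axis=1)  # linear interpolation
    raise ValueError(f"unknown feature function {func!r}")


def extract_feature_vector(
    window: dict[str, np.ndarray],
    registry: list[FeatureSpec] | None = None,
    all_autocorrelation: float = np.nan,
) -> np.ndarray:
    """Feature vector for a single aligned sub-window.

    The cross-channel autocorrelation is supplied by the caller because its
    lag spans the full observing window.
    """
    registry = registry if registry is not None else default_registry()
    out = np.empty(len(registry))
    for j, spec in enumerate(registry):
        if spec.function == "autocorr_agg":
            out[j] = all_autocorrelation
            continue
        x = np.asarray(window[spec.channel], dtype=float)
        if x.size == 0 or np.isnan(x).any():
            raise ValueError(f"incomplete {spec.channel} window")
        out[j] = _apply(spec.function, x[None, :], spec.params)[0]
    return out


def extract_sequence(
    record: PatientRecord,
    window_end: int,
    geometry: WindowGeometry | None = None,
    registry: list[FeatureSpec] | None = None,
) -> np.ndarray:
    """Feature sequence (n_steps x n_features) for the observing window
    ``[window_end - observing_window, window_end)``.

    Raises if the record does not cover the window.
    """
    geometry = geometry or WindowGeometry()
    registry = registry if registry is not None else default_registry()
    start = window_end - geometry.observing_window
    if start < 0 or window_end > record.n_minutes:
        raise ValueError(
            f"record {record.patient_id} (len {record.n_minutes}) does not cover "
            f"[{start}, {window_end})"
        )
    full = {c: record.channels[c].values[start:window_end] for c in CHANNELS}
    for c, x in full.items():
        if np.isnan(x).any():
            raise ValueError(f"channel {c} incomplete over the observing window")

    all_ac = float(
        np.mean([autocorrelation(full[c], geometry.autocorr_lag) for c in CHANNELS])
    )

    # stack sub-windows: (n_steps, sub_window) per channel
    idx = (
        np.arange(geometry.n_steps)[:, None] * geometry.step
        + np.arange(geometry.sub_window)[None, :]
    )
    windows = {c: full[c][idx] for c in CHANNELS}

    out = np.empty((geometry.n_steps, len(registry)))
    for j, spec in enumerate(registry):
        if spec.function == "autocorr_agg":
            out[:, j] = all_ac
        else:
            out[:, j] = _apply(spec.function, windows[spec.channel], spec.params)
    return out
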