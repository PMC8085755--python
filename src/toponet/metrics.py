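"""Discrimination metrics, bootstrap confidence intervals, grouped CV.

Six metrics summarise a risk score against binary onset labels: AUROC plus
five confusion-table metrics (sensitivity, specificity, accuracy, F1,
precision) at a decision threshold (default 0.5; predictions are score >
threshold). Confidence intervals are class-stratified percentile bootstrap,
applied uniformly to all six metrics. Cross-validation folds are grouped by
patient so windows from one admission never span folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

METRIC_NAMES = ("auroc", "sensitivity", "specificity", "accuracy", "f1", "precision")


@dataclass
class MetricReport:
    auroc: float
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    precision: float
    decision_threshold: float = 0.5
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {m: getattr(self, m) for m in METRIC_NAMES}
        d["decision_threshold"] = self.decision_threshold
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        if self.flags:
            d["flags"] = list(self.flags)
        return d


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def threshold_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """The six-metric report at ``score > threshold``.

    When no sample is predicted positive, precision (and hence F1) is
    undefined; both are reported as 0 with an explanatory flag.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    flags: list[str] = []
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    acc = (tp + tn) / (tp + tn + fp + fn)
    if tp + fp == 0:
        prec = 0.0
        flags.append("no-predicted-positives")
    else:
        prec = tp / (tp + fp)
    f1 = 0.0 if prec + sens == 0 else 2 * prec * sens / (prec + sens)
    return MetricReport(
        auroc=auroc(scores, labels),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        f1=f1,
        precision=prec,
        decision_threshold=threshold,
        flags=flags,
    )


def bootstrap_ci(
    scores,
    labels,
    metric,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric(scores, labels)``.

    Resampling is with replacement within each class (stratified), so every
    replicate contains both classes and the class ratio is preserved.
    """
    if B < 100:
        raise ValueError("B must be at least 100 for a percentile interval")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    stats = np.empty(B)
    for b in range(B):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, size=pos_idx.size, replace=True),
                rng.choice(neg_idx, size=neg_idx.size, replace=True),
            ]
        )
        stats[b] = metric(scores[idx], labels[idx])
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def report_with_cis(scores, labels, threshold: float = 0.5,
                    B: int = 1000, seed: int = 0) -> MetricReport:
    """Six-metric report with a bootstrap CI attached to every metric."""
    report = threshold_metrics(scores, labels, threshold)
    metric_fns = {
        "auroc": auroc,
        "sensitivity": lambda s, y: threshold_metrics(s, y, threshold).sensitivity,
        "specificity": lambda s, y: threshold_metrics(s, y, threshold).specificity,
        "accuracy": lambda s, y: threshold_metrics(s, y, threshold).accuracy,
        "f1": lambda s, y: threshold_metrics(s, y, threshold).f1,
        "precision": lambda s, y: threshold_metrics(s, y, threshold).precision,
    }
    for i, (name, fn) in enumerate(metric_fns.items()):
        report.ci[name] = bootstrap_ci(scores, labels, fn, B=B, seed=seed + i)
    return report


def patient_folds(patient_ids, k: int, seed: int) -> list[np.ndarray]:
    """Seeded patient-disjoint fold assignment: sample index arrays per fold."""
    patient_ids = np.asarray(patient_ids)
    unique = np.array(sorted(set(patient_ids.tolist())))
    if unique.size < k:
        raise ValueError(f"need at least {k} patients, got {unique.size}")
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    folds = []
    for chunk in np.array_split(unique, k):
        members = set(chunk.tolist())
        folds.append(np.flatnonzero([p in members for p in patient_ids]))
    return folds


def grouped_cv(samples, fit_predict, k: int = 5, seed: int = 0,
               threshold: float = 0.5):
    """Patient-grouped k-fold CV.

    ``fit_predict(train_samples, test_samples) -> scores`` encapsulates the
    model; this function only manages folds and scoring. Returns the per-fold
    MetricReports and a {metric: (mean, sd)} summary.
    """
    ids = [s.patient_id for s in samples]
    folds = patient_folds(ids, k, seed)
    reports = []
    for test_idx in folds:
        test_set = set(test_idx.tolist())
        train = [s for i, s in enumerate(samples) if i not in test_set]
        test = [samples[i] for i in test_idx]
        scores = fit_predict(train, test)
        labels = np.array([s.label for s in test])
        reports.append(threshold_metrics(scores, labels, threshold))
    summary = {
        m: (
            float(np.mean([getattr(r, m) for r in reports])),
            float(np.std([getattr(r, m) for r in reports], ddof=1)),
        )
        for m in METRIC_NAMES
    }
    return reports, summary
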