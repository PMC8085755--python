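"""End-to-end workflows: large-cohort pretraining and ward transfer.

``run_pretrain`` ties the stages together — label onsets, build balanced
labeled samples, optionally tune hyperparameters, train, and evaluate on
held-out patients with bootstrap confidence intervals. ``run_transfer``
finetunes a pretrained bundle on a small second cohort and reports
patient-grouped 5-fold cross-validation means and SDs. Every artifact
written to disk carries the hash of the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .metrics import METRIC_NAMES, grouped_cv
from .model import (ModelConfig, TachycardiaOnsetModel, TachycardiaOnsetResults,
                    TRANSFER_CONFIG)
from .sampling import SamplingConfig, balance_and_split, build_samples
from .vitals import preprocess_record, read_static_csv, read_vitals_csv

log = logging.getLogger("toponet")


@dataclass
class PipelineConfig:
    vitals_csv: str
    static_csv: str
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    tune_budget: int = 0          # 0 skips hyperparameter search
    bootstrap_B: int = 1000
    decision_threshold: float = 0.5
    seed: int = 0

    def hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_records(vitals_csv, static_csv):
    """Read + preprocess a cohort: forward-filled, channel-aligned records."""
    raw = read_vitals_csv(vitals_csv)
    profiles = read_static_csv(static_csv)
    records = []
    for pid, series in raw.items():
        if pid not in profiles:
            raise ValueError(f"patient {pid} has vitals but no static profile")
        records.append(preprocess_record(pid, series, profiles[pid]))
    log.info("loaded %d records", len(records))
    return records


def _report_dict(report, extra=None) -> dict:
    d = report.as_dict()
    if extra:
        d.update(extra)
    return d


def run_pretrain(config: PipelineConfig, out_dir=None):
    """Pretraining workflow; returns (results, report dict).

    When ``out_dir`` is given, writes the model bundle, the metrics report
    and the config (with its hash) for provenance.
    """
    records = load_records(config.vitals_csv, config.static_csv)
    samples = build_samples(records, config.sampling)
    n_pos = sum(s.label for s in samples)
    log.info("extracted %d samples (%d positive, %d negative)",
             len(samples), n_pos, len(samples) - n_pos)
    train, test = balance_and_split(samples, seed=config.seed)
    log.info("balanced+split: %d train / %d test samples", len(train), len(test))

    model = TachycardiaOnsetModel(train)
    model_config = config.model
    if config.tune_budget > 0:
        model_config, trials = model.random_search_cv(config.tune_budget,
                                                      seed=config.seed)
        log.info("random search over %d draws: lr=%g epochs=%d",
                 len(trials), model_config.learning_rate, model_config.epochs)
    results = model.fit(model_config)
    report = results.evaluate(test, threshold=config.decision_threshold,
                              with_ci=True, B=config.bootstrap_B, seed=config.seed)
    report_dict = _report_dict(report, {
        "n_train": len(train), "n_test": len(test),
        "forecast_range_hours": config.sampling.forecast_range,
        "config_hash": config.hash(),
    })
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.save(out / "model")
        (out / "report.json").write_text(json.dumps(report_dict, indent=1))
        (out / "pipeline.yaml").write_text(
            yaml.safe_dump({"hash": config.hash(), "config": asdict(config)}))
    return results, report_dict


def run_transfer(pretrained: TachycardiaOnsetResults | str,
                 config: PipelineConfig,
                 transfer_config: ModelConfig | None = None,
                 out_dir=None):
    """Transfer workflow: finetune + patient-grouped 5-fold CV report.

    ``pretrained`` is a results object or a bundle directory. Returns
    (finetuned results on the full ward sample set, report dict with
    per-metric mean and SD across folds).
    """
    if not isinstance(pretrained, TachycardiaOnsetResults):
        pretrained = TachycardiaOnsetResults.load(Path(pretrained) / "model")
    transfer_config = transfer_config or TRANSFER_CONFIG
    records = load_records(config.vitals_csv, config.static_csv)
    samples = build_samples(records, config.sampling)
    pos = [s for s in samples if s.label == 1]
    neg = [s for s in samples if s.label == 0]
    if not pos or not neg:
        raise ValueError("transfer cohort must contain both classes")
    rng = np.random.default_rng(config.seed)
    if len(neg) > len(pos):
        keep = sorted(rng.choice(len(neg), size=len(pos), replace=False))
        neg = [neg[i] for i in keep]
    balanced = pos + neg

    def fit_predict(train, test):
        return pretrained.finetune(train, transfer_config).predict(test)

    fold_reports, summary = grouped_cv(balanced, fit_predict, k=5,
                                       seed=config.seed,
                                       threshold=config.decision_threshold)
    finetuned = pretrained.finetune(balanced, transfer_config)
    report_dict = {
        m: {"mean": summary[m][0], "sd": summary[m][1]} for m in METRIC_NAMES
    }
    report_dict["n_samples"] = len(balanced)
    report_dict["config_hash"] = config.hash()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        finetuned.save(out / "model")
        (out / "report.json").write_text(json.dumps(report_dict, indent=1))
        (out / "pipeline.yaml").write_text(
            yaml.safe_dump({"hash": config.hash(), "config": asdict(config)}))
    return finetuned, report_dict
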