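"""The tachycardia-onset sequence classifier.

Statsmodels-style surface: :class:`TachycardiaOnsetModel` is built from
labeled samples and ``fit()`` returns a :class:`TachycardiaOnsetResults`
carrying the trained weights, the training-set normalisation statistics,
the config, the loss history and a ``summary()`` table. Prediction,
evaluation, transfer finetuning and serialisation hang off the results
object.

Each sample is a (21 steps x 21 features) sequence plus an 11-value static
vector (age, gender, admission type, first care unit, cardiovascular
history). The static vector is appended to every time step, the fused
per-step vectors are z-scored with statistics computed on training data
only, and a bidirectional LSTM (hidden size 32 per direction) maps the
sequence to an onset risk probability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .features import FEATURE_NAMES
from .metrics import MetricReport, report_with_cis, threshold_metrics
from .vitals import ADMISSION_TYPES, CARE_UNITS, StaticProfile

STATIC_FIELDS = (
    ("age",)
    + ("gender_male",)
    + tuple(f"admission_{t}" for t in ADMISSION_TYPES)
    + tuple(f"unit_{u}" for u in CARE_UNITS)
    + ("cvd_history",)
)  # 11 values

#: hyperparameter grids for random search (learning rate 1e-4..1e-2 step
#: 1e-4; epochs 5..95 step 10)
LR_GRID = np.round(np.arange(1, 101) * 1e-4, 6)
EPOCH_GRID = tuple(range(5, 101, 10))


def encode_static(profile: StaticProfile) -> np.ndarray:
    """Encode a static profile as an 11-value numeric vector.

    Age is numeric; gender is a single male indicator; admission type and
    first care unit are one-hot (the care-unit block is all zero for
    general-ward patients with no unit); cardiovascular history is 0/1.
    """
    v = np.zeros(len(STATIC_FIELDS))
    v[0] = profile.age
    v[1] = 1.0 if profile.gender == "male" else 0.0
    v[2 + ADMISSION_TYPES.index(profile.admission_type)] = 1.0
    if profile.first_care_unit is not None:
        v[5 + CARE_UNITS.index(profile.first_care_unit)] = 1.0
    v[10] = 1.0 if profile.cvd_history else 0.0
    return v


@dataclass(frozen=True)
class ModelConfig:
    hidden_size: int = 32      # per direction
    learning_rate: float = 2e-4
    epochs: int = 20
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs < 0 or self.batch_size < 1:
            raise ValueError("learning_rate and batch_size must be positive, epochs >= 0")


#: finetuning defaults for transfer to a small cohort
TRANSFER_CONFIG = ModelConfig(learning_rate=2e-4, epochs=18, batch_size=32)


@dataclass
class NormalizationStats:
    """Per-feature z-scoring statistics, computed on training data only.

    Zero-variance features (e.g. constant indicator columns) keep std 1 so
    they pass through unscaled.
    """

    seq_mean: np.ndarray
    seq_std: np.ndarray
    static_mean: np.ndarray
    static_std: np.ndarray

    @classmethod
    def fit(cls, X_seq: np.ndarray, X_static: np.ndarray) -> "NormalizationStats":
        seq_mean = X_seq.mean(axis=(0, 1))
        seq_std = X_seq.std(axis=(0, 1))
        seq_std[seq_std == 0] = 1.0
        static_mean = np.zeros(X_static.shape[1])
        static_std = np.ones(X_static.shape[1])
        # only the numeric static field (age) is scaled; indicators pass through
        static_mean[0] = X_static[:, 0].mean()
        sd = X_static[:, 0].std()
        static_std[0] = sd if sd > 0 else 1.0
        return cls(seq_mean, seq_std, static_mean, static_std)

    def transform(self, X_seq: np.ndarray, X_static: np.ndarray):
        return (
            (X_seq - self.seq_mean) / self.seq_std,
            (X_static - self.static_mean) / self.static_std,
        )


def registry_hash(feature_names=FEATURE_NAMES) -> str:
    payload = ",".join(feature_names) + "|" + ",".join(STATIC_FIELDS)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stack(samples):
    X_seq = np.stack([np.asarray(s.features, dtype=float) for s in samples])
    X_static = np.stack([np.asarray(s.static_vector, dtype=float) for s in samples])
    y = np.array([s.label for s in samples], dtype=float)
    return X_seq, X_static, y


def _fuse(X_seq: np.ndarray, X_static: np.ndarray) -> np.ndarray:
    """Append the static vector to every time step: (N,T,F) -> (N,T,F+S)."""
    T = X_seq.shape[1]
    tiled = np.repeat(X_static[:, None, :], T, axis=1)
    return np.concatenate([X_seq, tiled], axis=2)


class TachycardiaOnsetModel:
    """Binary onset-risk model over windowed vital-sign feature sequences.

    Parameters
    ----------
    samples
        Labeled samples (objects with ``features``, ``static_vector``,
        ``label`` and ``patient_id`` attributes), e.g. from
        :mod:`toponet.sampling`.
    """

    def __init__(self, samples):
        samples = list(samples)
        if not samples:
            raise ValueError("no samples")
        shapes = {np.asarray(s.features).shape for s in samples}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent feature shapes: {shapes}")
        self.samples = samples
        self.registry_hash = registry_hash()

    @property
    def patient_ids(self) -> list[str]:
        return [s.patient_id for s in self.samples]

    def fit(
        self,
        config: ModelConfig | None = None,
        warm_start: dict[str, np.ndarray] | None = None,
        norm: NormalizationStats | None = None,
    ) -> "TachycardiaOnsetResults":
        """Train the classifier; seeded and fully deterministic.

        ``warm_start`` continues optimisation from existing weights
        (transfer finetuning); normalisation statistics are recomputed on
        the new training data unless ``norm`` is given.
        """
        config = config or ModelConfig()
        X_seq, X_static, y = _stack(self.samples)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        norm = norm or NormalizationStats.fit(X_seq, X_static)
        X = _fuse(*norm.transform(X_seq, X_static))
        if warm_start is not None:
            params = {k: v.copy() for k, v in warm_start.items()}
            expected = X.shape[2]
            if params["Wx_fw"].shape[0] != expected:
                raise ValueError(
                    f"architecture mismatch: pretrained input dim "
                    f"{params['Wx_fw'].shape[0]}, data dim {expected}"
                )
        else:
            params = nn.init_params(X.shape[2], config.hidden_size, config.seed)
        history = nn.train_loop(
            params, X, y, config.learning_rate, config.epochs, config.batch_size,
            seed=config.seed,
        )
        return TachycardiaOnsetResults(params, norm, config, self.registry_hash, history)

    def random_search_cv(self, budget: int, seed: int = 0, k: int = 5):
        """Random hyperparameter search with patient-grouped k-fold CV.

        Samples (learning rate, epochs) uniformly from the grids, scores
        each draw by mean validation cross-entropy over the folds, and
        returns ``(best_config, trials)`` with trials sorted as drawn.
        """
        from .metrics import patient_folds  # local import avoids cycle at module load

        if budget < 1:
            raise ValueError("budget must be >= 1")
        folds = patient_folds(self.patient_ids, k, seed)
        rng = np.random.default_rng(seed)
        trials = []
        best = None
        for _ in range(budget):
            cfg = ModelConfig(
                learning_rate=float(rng.choice(LR_GRID)),
                epochs=int(rng.choice(EPOCH_GRID)),
                seed=seed,
            )
            losses = []
            for test_idx in folds:
                test_set = set(test_idx.tolist())
                train = [s for i, s in enumerate(self.samples) if i not in test_set]
                val = [self.samples[i] for i in test_idx]
                yv = np.array([s.label for s in val], dtype=float)
                if len(np.unique([s.label for s in train])) < 2 or yv.size == 0:
                    continue
                res = TachycardiaOnsetModel(train).fit(cfg)
                p = np.clip(res.predict(val), 1e-12, 1 - 1e-12)
                losses.append(float(-np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p))))
            mean_loss = float(np.mean(losses)) if losses else np.inf
            trials.append({"learning_rate": cfg.learning_rate, "epochs": cfg.epochs,
                           "val_loss": mean_loss})
            if best is None or mean_loss < best[1]:
                best = (cfg, mean_loss)
        return best[0], trials


class TachycardiaOnsetResults:
    """Fitted classifier: weights, normalisation stats, config, diagnostics."""

    def __init__(self, params, norm: NormalizationStats, config: ModelConfig,
                 reg_hash: str, history: list[float]):
        self.params = params
        self.norm = norm
        self.config = config
        self.registry_hash = reg_hash
        self.history = history

    # -- inference ---------------------------------------------------------

    def predict_arrays(self, X_seq: np.ndarray, X_static: np.ndarray) -> np.ndarray:
        """Risk scores in [0, 1]; normalisation uses stored training stats."""
        X_seq = np.asarray(X_seq, dtype=float)
        X_static = np.asarray(X_static, dtype=float)
        if X_seq.ndim == 2:
            X_seq, X_static = X_seq[None], X_static[None]
        if X_seq.shape[2] != self.norm.seq_mean.size:
            raise ValueError(
                f"expected {self.norm.seq_mean.size} sequence features, "
                f"got {X_seq.shape[2]}"
            )
        X = _fuse(*self.norm.transform(X_seq, X_static))
        return nn.forward(self.params, X)

    def predict(self, samples) -> np.ndarray:
        X_seq, X_static, _ = _stack(list(samples))
        return self.predict_arrays(X_seq, X_static)

    # -- evaluation --------------------------------------------------------

    def evaluate(self, samples, threshold: float = 0.5,
                 with_ci: bool = False, B: int = 1000, seed: int = 0) -> MetricReport:
        samples = list(samples)
        scores = self.predict(samples)
        labels = np.array([s.label for s in samples])
        if with_ci:
            return report_with_cis(scores, labels, threshold, B=B, seed=seed)
        return threshold_metrics(scores, labels, threshold)

    # -- transfer ----------------------------------------------------------

    def finetune(self, new_samples, config: ModelConfig | None = None
                 ) -> "TachycardiaOnsetResults":
        """Continue training from these weights on a new cohort.

        Defaults to the transfer recipe (lr 2e-4, 18 epochs, batch 32).
        Normalisation statistics are recomputed on the new training data.
        With 0 finetuning epochs the weights are returned unchanged.
        """
        config = config or replace(TRANSFER_CONFIG, seed=self.config.seed)
        model = TachycardiaOnsetModel(new_samples)
        if model.registry_hash != self.registry_hash:
            raise ValueError("feature registry mismatch between model and new samples")
        if config.epochs == 0:
            X_seq, X_static, _ = _stack(model.samples)
            norm = NormalizationStats.fit(X_seq, X_static)
            return TachycardiaOnsetResults(
                {k: v.copy() for k, v in self.params.items()},
                norm, config, self.registry_hash, [])
        return model.fit(config, warm_start=self.params)

    # -- presentation ------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Tachycardia onset model (bidirectional LSTM)",
            "=" * 46,
            f"hidden size (per direction): {self.config.hidden_size}",
            f"learning rate:               {self.config.learning_rate:g}",
            f"epochs:                      {self.config.epochs}",
            f"batch size:                  {self.config.batch_size}",
            f"seed:                        {self.config.seed}",
            f"feature registry hash:       {self.registry_hash}",
            f"trainable parameters:        {sum(v.size for v in self.params.values())}",
        ]
        if self.history:
            lines.append(f"final training loss:         {self.history[-1]:.4f}")
        return "\n".join(lines)

    # -- serialisation (directory bundle) ----------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.params)
        stats = {
            "seq_mean": self.norm.seq_mean.tolist(),
            "seq_std": self.norm.seq_std.tolist(),
            "static_mean": self.norm.static_mean.tolist(),
            "static_std": self.norm.static_std.tolist(),
        }
        (d / "normalization.json").write_text(json.dumps(stats, indent=1))
        cfg = {
            "hidden_size": self.config.hidden_size,
            "learning_rate": self.config.learning_rate,
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "seed": self.config.seed,
            "registry_hash": self.registry_hash,
            "history": self.history,
        }
        (d / "config.yaml").write_text(yaml.safe_dump(cfg))

    @classmethod
    def load(cls, directory) -> "TachycardiaOnsetResults":
        d = Path(directory)
        with np.load(d / "weights.npz") as z:
            params = {k: z[k].copy() for k in z.files}
        stats = json.loads((d / "normalization.json").read_text())
        norm = NormalizationStats(**{k: np.array(v) for k, v in stats.items()})
        cfg = yaml.safe_load((d / "config.yaml").read_text())
        config = ModelConfig(
            hidden_size=cfg["hidden_size"], learning_rate=cfg["learning_rate"],
            epochs=cfg["epochs"], batch_size=cfg["batch_size"], seed=cfg["seed"],
        )
        return cls(params, norm, config, cfg["registry_hash"], cfg.get("history", []))
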