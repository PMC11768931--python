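"""Training loop, metric suite, and the raw-vs-spectrogram comparison harness.

Training is plain mini-batch Adam with per-epoch validation and
best-validation-accuracy checkpointing; everything is deterministic given the
config seed. Per-class "accuracy" is the recall of that class (the standard
reading of class-wise accuracy off a confusion matrix).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.metrics import precision_recall_fscore_support

from .audio import AudioClip, ValidationError, split_counts
from .nn import Adam, Classifier, count_parameters, estimate_flops, reseed_dropout
from .nn import serialized_size_bytes, softmax_cross_entropy
from . import augment as aug
from . import features as feat
from . import models as mdl
from . import synthetic as syn


@dataclass
class ArrayDataset:
    """Fixed-shape inputs with integer class labels."""

    x: np.ndarray
    y: np.ndarray
    classes: tuple[str, ...] = ("roar", "rumble", "trumpet")

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int64)
        if len(self.x) != len(self.y):
            raise ValidationError("inputs and labels must have equal length")

    def __len__(self) -> int:
        return len(self.x)


def clips_to_dataset(clips: list[AudioClip],
                     classes: tuple[str, ...] = ("roar", "rumble", "trumpet")) -> ArrayDataset:
    index = {c: i for i, c in enumerate(classes)}
    x = np.stack([c.samples for c in clips])
    y = np.array([index[c.label] for c in clips])
    return ArrayDataset(x, y, classes)


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    train_batch: int = 32
    val_batch: int = 8
    epochs: int = 60
    seed: int = 0
    weight_decay: float = 0.0
    patience: int | None = None  # early stopping off by default

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.train_batch < 1 or self.val_batch < 1:
            raise ValidationError("batch sizes must be >= 1")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")


# Table-style per-model defaults for the raw-audio pipeline.
DEFAULT_LEARNING_RATES = {
    "yamnet": 2e-4,
    "rawnet": 5.90e-3,
    "mobilenet_v2": 5.52e-4,
    "elephant_caller_net": 5e-4,
}


@dataclass
class LearningCurves:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_loss) + 1),
            "train_loss": self.train_loss, "train_accuracy": self.train_accuracy,
            "val_loss": self.val_loss, "val_accuracy": self.val_accuracy,
        })


@dataclass
class TrainResult:
    model: Classifier
    curves: LearningCurves
    best_val_accuracy: float
    best_epoch: int


def _batched_eval(model: Classifier, data: ArrayDataset, batch: int) -> tuple[float, float]:
    model.eval()
    losses, correct = [], 0
    for i in range(0, len(data), batch):
        xb, yb = data.x[i:i + batch], data.y[i:i + batch]
        logits = model.forward_logits(xb)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(data)), correct / len(data)


def train(model: Classifier, train_set: ArrayDataset, val_set: ArrayDataset,
          config: TrainConfig) -> TrainResult:
    """Mini-batch training with per-epoch validation and best checkpointing."""
    config.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValidationError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.seed)
    reseed_dropout(model, config.seed)
    net = model.net if hasattr(model, "net") else model
    opt = Adam(model.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    curves = LearningCurves()
    best_acc, best_epoch, best_state = -1.0, 0, None
    bad_epochs = 0

    for epoch in range(1, config.epochs + 1):
        model.train()
        order = rng.permutation(len(train_set))
        ep_loss, ep_correct = 0.0, 0
        for bi, start in enumerate(range(0, len(order), config.train_batch)):
            idx = order[start:start + config.train_batch]
            xb, yb = train_set.x[idx], train_set.y[idx]
            logits = model.forward_logits(xb)
            loss, glogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss (lr={config.learning_rate}, "
                    f"epoch={epoch}, batch={bi})")
            opt.zero_grad()
            model.backward(glogits)
            opt.step()
            ep_loss += loss * len(idx)
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
        curves.train_loss.append(ep_loss / len(train_set))
        curves.train_accuracy.append(ep_correct / len(train_set))

        v_loss, v_acc = _batched_eval(model, val_set, config.val_batch)
        curves.val_loss.append(v_loss)
        curves.val_accuracy.append(v_acc)

        if v_acc > best_acc:
            best_acc, best_epoch = v_acc, epoch
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if config.patience is not None and bad_epochs > config.patience:
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return TrainResult(model=model, curves=curves,
                       best_val_accuracy=best_acc, best_epoch=best_epoch)


# ---------------------------------------------------------------------------
# Evaluation report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    confusion_matrix: np.ndarray  # rows = true class
    classes: tuple[str, ...]
    overall_accuracy: float
    per_class_accuracy: dict[str, float]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]

    def to_dict(self) -> dict[str, Any]:
        return {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "classes": list(self.classes),
            "overall_accuracy": self.overall_accuracy,
            "per_class_accuracy": self.per_class_accuracy,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            classes: tuple[str, ...]) -> EvalReport:
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValidationError("cannot evaluate on an empty test set")
    label_ids = np.arange(len(classes))
    cm = sk_confusion_matrix(y_true, y_pred, labels=label_ids)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=label_ids, zero_division=0)
    overall = float(np.trace(cm) / len(y_true))
    return EvalReport(
        confusion_matrix=cm, classes=classes, overall_accuracy=overall,
        per_class_accuracy={c: float(recall[i]) for i, c in enumerate(classes)},
        precision={c: float(precision[i]) for i, c in enumerate(classes)},
        recall={c: float(recall[i]) for i, c in enumerate(classes)},
        f1={c: float(f1[i]) for i, c in enumerate(classes)},
    )


def evaluate(model: Classifier, test_set: ArrayDataset, batch: int = 8) -> EvalReport:
    if len(test_set) == 0:
        raise ValidationError("cannot evaluate on an empty test set")
    model.eval()
    preds = []
    for i in range(0, len(test_set), batch):
        preds.append(model.predict(test_set.x[i:i + batch]))
    return report_from_predictions(test_set.y, np.concatenate(preds), test_set.classes)


# ---------------------------------------------------------------------------
# Comparison harness
# ---------------------------------------------------------------------------

RAW_MODEL_BUILDERS: dict[str, Callable[..., Classifier]] = {
    "elephant_caller_net": lambda n, seed: mdl.build_elephant_caller_net(
        mdl.ElephantCallerNetConfig(input_samples=n), seed=seed),
    "mobilenet_v2": lambda n, seed: mdl.build_mobilenet_v2_raw(
        input_samples=n, seed=seed),
    "yamnet": lambda n, seed: mdl.build_yamnet_1d(seed=seed),
    "rawnet": lambda n, seed: mdl.build_rawnet_residual(seed=seed),
}

REGIMES = ("none", "approach1", "approach2")


@dataclass
class ComparisonSpec:
    """Desk-scale raw-vs-spectrogram / augmentation-regime experiment grid."""

    pipelines: tuple[str, ...] = ("raw",)
    models: tuple[str, ...] = ("elephant_caller_net",)
    regimes: tuple[str, ...] = ("none",)
    seeds: tuple[int, ...] = (0,)
    clips_per_class: int = 30
    duration_s: float = 1.5
    sample_rate: int = 4000
    epochs: int = 20
    train_batch: int = 8
    learning_rate: float | None = None

    def validate(self) -> None:
        for p in self.pipelines:
            if p not in ("raw", "spectrogram"):
                raise ValidationError(f"unknown pipeline {p!r}")
        for m in self.models:
            if m not in RAW_MODEL_BUILDERS and m not in ("cnn2d", "svm"):
                raise ValidationError(f"unknown model {m!r}")
        for r in self.regimes:
            if r not in REGIMES:
                raise ValidationError(f"unknown augmentation regime {r!r}")


def synthetic_split_clips(clips_per_class: int, duration_s: float, sample_rate: int,
                          seed: int, ratios=(0.8, 0.1, 0.1)) -> dict[str, list[AudioClip]]:
    """Generate per-class synthetic clips and split them stratified in memory."""
    cfg = syn.SyntheticDatasetConfig(
        per_class_counts={lab: clips_per_class for lab in syn.LABELS},
        specs=syn.default_specs(duration_s, sample_rate), seed=seed)
    rng = np.random.default_rng(seed + 1)
    out: dict[str, list[AudioClip]] = {"train": [], "val": [], "test": []}
    clips = syn.generate_clips(cfg)
    for label in syn.LABELS:
        members = [c for c in clips if c.label == label]
        n_train, n_val, n_test = split_counts(len(members), ratios)
        order = rng.permutation(len(members))
        for rank, i in enumerate(order):
            tag = ("train" if rank < n_train
                   else "val" if rank < n_train + n_val else "test")
            out[tag].append(members[i])
    return out


def _apply_regime(splits: dict[str, list[AudioClip]], regime: str,
                  seed: int) -> dict[str, list[AudioClip]]:
    if regime == "none":
        return splits
    out = dict(splits)
    if regime == "approach1":
        out["train"] = aug.balance_clips(splits["train"], seed=seed)
    else:  # approach2: train and validation expand fivefold; test untouched
        out["train"] = aug.expand_clips_fourfold(splits["train"], seed=seed)
        out["val"] = aug.expand_clips_fourfold(splits["val"], seed=seed + 1)
    return out


def _feature_datasets(splits: dict[str, list[AudioClip]]) -> dict[str, ArrayDataset]:
    cfg = feat.FeatureConfig()
    images = {k: [feat.build_feature_image(c, cfg) for c in v] for k, v in splits.items()}
    norm = feat.FeatureNormalizer().fit(images["train"])
    index = {c: i for i, c in enumerate(syn.LABELS)}
    out = {}
    for k, imgs in images.items():
        data = np.stack([norm.transform(i).stacked for i in imgs])
        y = np.array([index[i.label] for i in imgs])
        out[k] = ArrayDataset(data, y, syn.LABELS)
    return out


def run_comparison(spec: ComparisonSpec) -> tuple[pd.DataFrame, dict[str, Any]]:
    """One row per (pipeline, model, regime, seed); reproducible per seed.

    Returns the comparison table and an artifacts dict holding, per run, the
    training-manifest label counts and the learning curves.
    """
    spec.validate()
    rows, artifacts = [], {}
    for pipeline in spec.pipelines:
        for model_name in spec.models:
            for regime in spec.regimes:
                for seed in spec.seeds:
                    row, art = _run_one(spec, pipeline, model_name, regime, seed)
                    rows.append(row)
                    artifacts[row["run_id"]] = art
    table = pd.DataFrame(rows)
    return table, artifacts


def _run_one(spec: ComparisonSpec, pipeline: str, model_name: str,
             regime: str, seed: int) -> tuple[dict, dict]:
    splits = synthetic_split_clips(spec.clips_per_class, spec.duration_s,
                                   spec.sample_rate, seed)
    splits = _apply_regime(splits, regime, seed)
    train_counts = pd.Series([c.label for c in splits["train"]]).value_counts().to_dict()
    run_id = f"{pipeline}:{model_name}:{regime}:{seed}"
    n_samples = round(spec.duration_s * spec.sample_rate)

    if pipeline == "raw":
        if model_name not in RAW_MODEL_BUILDERS:
            raise ValidationError(f"model {model_name!r} is not a raw-audio model")
        model = RAW_MODEL_BUILDERS[model_name](n_samples, seed)
        data = {k: clips_to_dataset(v) for k, v in splits.items()}
        input_shape: tuple[int, ...] = (n_samples,)
    elif model_name == "svm":
        data = _feature_datasets(splits)
        flat = {k: d.x.reshape(len(d), -1) for k, d in data.items()}
        clf = mdl.fit_svm_spectral(flat["train"], data["train"].y)
        report = report_from_predictions(data["test"].y, clf.predict(flat["test"]),
                                         syn.LABELS)
        row = {"run_id": run_id, "pipeline": pipeline, "model": model_name,
               "regime": regime, "seed": seed, "accuracy": report.overall_accuracy,
               "parameter_count": int(sum(sv.size for sv in clf.support_vectors_)),
               "model_size_bytes": int(clf.support_vectors_.nbytes),
               "gflops_per_input": np.nan}
        return row, {"train_counts": train_counts, "report": report.to_dict()}
    else:
        data = _feature_datasets(splits)
        model = mdl.build_spectrogram_cnn(data["train"].x.shape[1:], seed=seed)
        input_shape = data["train"].x.shape[1:]

    lr = spec.learning_rate or DEFAULT_LEARNING_RATES.get(model_name, 1e-3)
    cfg = TrainConfig(learning_rate=lr, train_batch=spec.train_batch,
                      epochs=spec.epochs, seed=seed)
    result = train(model, data["train"], data["val"], cfg)
    report = evaluate(result.model, data["test"])
    est = estimate_flops(model, input_shape)
    row = {"run_id": run_id, "pipeline": pipeline, "model": model_name,
           "regime": regime, "seed": seed, "accuracy": report.overall_accuracy,
           "parameter_count": count_parameters(model),
           "model_size_bytes": serialized_size_bytes(model),
           "gflops_per_input": est.per_input / 1e9}
    art = {"train_counts": train_counts, "report": report.to_dict(),
           "curves": result.curves.to_frame()}
    return row, art
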