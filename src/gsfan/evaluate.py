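"""Accuracy, confusion matrices, ablation sweeps and per-subject reports.

The two ablations mirror the model's design questions: how many
edge-convolution layers to stack (receptive field vs. over-smoothing)
and how large the per-point embedding should be (representation power
vs. overfitting).  Every sweep trains fresh models for each setting and
seed with all other hyperparameters held fixed, and uses the *same*
train/test split per seed across settings (paired design), so that
setting comparisons are not confounded by split noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .hand import N_CLASSES
from .io import split_dataset
from .model import GSFANClassifier, ModelConfig, TrainConfig, train

__all__ = [
    "EvalReport",
    "SweepResult",
    "accuracy",
    "confusion_matrix",
    "evaluate_model",
    "sweep_layers",
    "sweep_dims",
    "per_subject_eval",
]


def accuracy(preds, labels) -> float:
    """Fraction of exact matches between predictions and labels."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have the same length")
    if preds.size == 0:
        raise ValueError("cannot compute accuracy of an empty set")
    return float(_skm.accuracy_score(labels, preds))


def confusion_matrix(preds, labels, n_classes: int = N_CLASSES) -> np.ndarray:
    """Counts with rows = true class, columns = predicted class."""
    preds = np.asarray(preds, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if preds.shape != labels.shape:
        raise ValueError("preds and labels must have the same length")
    for name, arr in (("preds", preds), ("labels", labels)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contain values outside [0, {n_classes})")
    return _skm.confusion_matrix(labels, preds, labels=np.arange(n_classes))


@dataclass
class EvalReport:
    """Overall/per-class accuracy and the confusion matrix of one test set."""

    overall_accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray
    n_test: int


def evaluate_model(clf: GSFANClassifier, clouds, n_classes: int = N_CLASSES) -> EvalReport:
    labels = np.asarray([c.label for c in clouds], dtype=int)
    preds = np.asarray(clf.predict([c.coords for c in clouds]), dtype=int)
    conf = confusion_matrix(preds, labels, n_classes)
    row_sums = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_sums > 0, np.diag(conf) / row_sums, np.nan)
    return EvalReport(
        overall_accuracy=accuracy(preds, labels),
        per_class_accuracy=per_class,
        confusion=conf,
        n_test=len(clouds),
    )


@dataclass
class SweepResult:
    """Per-(setting, seed) accuracies of one ablation sweep."""

    parameter: str
    records: pd.DataFrame
    summary: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        grouped = self.records.groupby("setting")["accuracy"]
        self.summary = grouped.agg(mean="mean", sd="std").reset_index()

    @property
    def best_setting(self):
        """Setting with the highest mean accuracy (smallest value on ties)."""
        s = self.summary.sort_values(["mean", "setting"], ascending=[False, True])
        return s.iloc[0]["setting"]


def _run_sweep(
    parameter: str,
    settings,
    make_model_config,
    dataset,
    n_seeds: int,
    train_config: TrainConfig | None,
    split_fraction: float,
) -> SweepResult:
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    base_train = train_config or TrainConfig()
    records = []
    for seed in range(n_seeds):
        split = split_dataset(dataset, fraction=split_fraction,
                              seed=base_train.seed + 1000 * seed)
        for setting in settings:
            mc = make_model_config(setting)
            tc = TrainConfig(
                learning_rate=base_train.learning_rate,
                batch_size=base_train.batch_size,
                momentum=base_train.momentum,
                epochs=base_train.epochs,
                seed=base_train.seed + 1000 * seed,
            )
            clf, _ = train(split, mc, tc)
            report = evaluate_model(clf, split.test)
            records.append(
                {"setting": setting, "seed": seed, "accuracy": report.overall_accuracy}
            )
    return SweepResult(parameter=parameter, records=pd.DataFrame(records))


def sweep_layers(
    dataset,
    layer_counts=(1, 2, 3, 4, 5),
    n_seeds: int = 3,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    split_fraction: float = 0.75,
) -> SweepResult:
    """Train/evaluate at each edge-convolution depth, all else fixed."""
    base = model_config or ModelConfig()

    def make(count):
        return ModelConfig(
            n_edgeconv_layers=count,
            k=base.k,
            edgeconv_dims=None,
            target_dim=base.target_dim,
            hidden_dim=base.hidden_dim,
            dropout_rate=base.dropout_rate,
            leaky_slope=base.leaky_slope,
            n_classes=base.n_classes,
            dynamic_graph=base.dynamic_graph,
            concat_layers=base.concat_layers,
            pool=base.pool,
            gate_location=base.gate_location,
        )

    return _run_sweep("n_edgeconv_layers", list(layer_counts), make, dataset,
                      n_seeds, train_config, split_fraction)


def sweep_dims(
    dataset,
    dims=(32, 64, 128, 256, 512, 1024, 2048),
    n_seeds: int = 3,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    split_fraction: float = 0.75,
) -> SweepResult:
    """Train/evaluate at each embedding dimension, all else fixed."""
    base = model_config or ModelConfig()

    def make(dim):
        return ModelConfig(
            n_edgeconv_layers=base.n_edgeconv_layers,
            k=base.k,
            edgeconv_dims=base.edgeconv_dims,
            target_dim=int(dim),
            hidden_dim=base.hidden_dim,
            dropout_rate=base.dropout_rate,
            leaky_slope=base.leaky_slope,
            n_classes=base.n_classes,
            dynamic_graph=base.dynamic_graph,
            concat_layers=base.concat_layers,
            pool=base.pool,
            gate_location=base.gate_location,
        )

    return _run_sweep("target_dim", list(dims), make, dataset,
                      n_seeds, train_config, split_fraction)


def per_subject_eval(
    dataset,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    split_fraction: float = 0.75,
    cross_subject: bool = False,
):
    """Evaluate per subject; returns ({subject: EvalReport}, mean accuracy).

    Default protocol trains and tests within each subject's own clouds.
    With ``cross_subject=True`` a leave-one-subject-out protocol is used:
    the model is trained on every other subject and tested on the held-out
    one.
    """
    dataset = list(dataset)
    subjects = sorted({c.subject_id for c in dataset})
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    reports = {}
    for subject in subjects:
        mine = [c for c in dataset if c.subject_id == subject]
        if len(mine) < N_CLASSES:
            warnings.warn(f"subject {subject} has fewer than {N_CLASSES} clouds; skipped")
            continue
        if cross_subject:
            others = [c for c in dataset if c.subject_id != subject]
            from .io import DatasetSplit

            split = DatasetSplit(train=others, test=mine,
                                 split_fraction=split_fraction, seed=train_config.seed)
        else:
            split = split_dataset(mine, fraction=split_fraction, seed=train_config.seed)
        clf, _ = train(split, model_config, train_config)
        reports[subject] = evaluate_model(clf, split.test)
    if not reports:
        raise ValueError("no subject had enough clouds to evaluate")
    mean_acc = float(np.mean([r.overall_accuracy for r in reports.values()]))
    return reports, mean_acc
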