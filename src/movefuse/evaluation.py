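"""Repeated stratified holdout evaluation, uniaxial baselines, and the
random-classification baseline.

The protocol: split the ensemble at random into ~80% training / 20% test,
fit the classifier (DTW templates or CNNs) on the training fold, score
the test fold, and repeat; the mean test accuracy over repetitions is the
reported estimate.  Splits are stratified per class so no training fold
is ever missing a class.  A single master seed drives every repetition,
so a report is byte-identical when re-run.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_model import MovementRecording, compute_target_lengths, minmax_fit
from .dtw_classifiers import fit_templates, dtw_classify
from .cnn import TrainingConfig, train_model, cnn_classify

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "repeated_holdout",
    "uniaxial_baseline",
    "random_baseline",
    "fusion_vs_uniaxial_summary",
    "data_digest",
]

_DTW_INPUT = {"dtw1": "VI", "dtw2": "LMI", "dtw3": "GMI"}
_CNN_INPUT = {"cnn1": "CNN1", "cnn2": "CNN2", "cnn3": "CNN3", "cnn4": "CNN4"}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier tag plus its options.

    ``model`` is one of dtw1/dtw2/dtw3/cnn1/cnn2/cnn3/cnn4; the
    input-model pairing (VI/LMI/GMI/GCI) is fixed by the tag.
    """

    model: str
    metric: str = "euclidean"
    estimator: str = "mean"
    amplitude_mode: str = "none"
    hyper: TrainingConfig | None = None

    @property
    def family(self) -> str:
        return "dtw" if self.model.startswith("dtw") else "cnn"

    def __post_init__(self):
        if self.model not in _DTW_INPUT and self.model not in _CNN_INPUT:
            raise ValueError(
                f"unknown classifier {self.model!r}; valid: "
                f"{sorted(_DTW_INPUT) + sorted(_CNN_INPUT)}"
            )


@dataclass
class EvaluationReport:
    classifier: str
    accuracies: list[float]            # per-repetition test accuracy, %
    mean_accuracy: float
    labels: list[int]
    confusion: list[list[int]]         # summed over repetitions; rows = truth
    master_seed: int
    train_frac: float
    reps: int
    config_digest: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


def data_digest(data: Sequence[MovementRecording]) -> str:
    """Content hash of an ensemble (labels + raw samples)."""
    h = hashlib.sha256()
    for rec in data:
        h.update(str(rec.label).encode())
        for s in rec.signals:
            h.update(np.ascontiguousarray(s.samples).tobytes())
    return h.hexdigest()[:16]


def _stratified_split(labels: np.ndarray, train_frac: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for lb in np.unique(labels):
        idx = np.flatnonzero(labels == lb)
        if idx.size < 2:
            raise ValueError(f"class {lb} has < 2 recordings; cannot stratify")
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def _fit_and_score(train, test, spec: ClassifierSpec, seed: int,
                   labels: list[int], confusion: np.ndarray) -> float:
    norm = compute_target_lengths(train, "GMI", amplitude_mode=spec.amplitude_mode)
    if spec.amplitude_mode == "minmax_per_axis":
        minmax_fit(train, norm)
    pos = {lb: i for i, lb in enumerate(labels)}
    correct = 0
    if spec.family == "dtw":
        templates = fit_templates(train, _DTW_INPUT[spec.model], norm,
                                  estimator_tag=spec.estimator)
        for rec in test:
            pred, _ = dtw_classify(rec, templates, norm, metric=spec.metric)
            confusion[pos[rec.label], pos[pred]] += 1
            correct += pred == rec.label
    else:
        ensemble = train_model(train, _CNN_INPUT[spec.model], norm,
                               hyper=spec.hyper, seed=seed)
        for rec in test:
            pred, _ = cnn_classify(rec, ensemble, norm)
            confusion[pos[rec.label], pos[pred]] += 1
            correct += pred == rec.label
    return 100.0 * correct / len(test)


def repeated_holdout(
    data: Sequence[MovementRecording],
    classifier_spec: ClassifierSpec,
    train_frac: float = 0.8,
    reps: int = 100,
    master_seed: int = 0,
) -> EvaluationReport:
    """Repeated stratified random holdout; returns the mean test accuracy
    over repetitions plus a confusion matrix summed over them."""
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    labels_arr = np.array([rec.label for rec in data])
    labels = sorted(np.unique(labels_arr).tolist())
    confusion = np.zeros((len(labels), len(labels)), dtype=int)
    accs = []
    for r in range(reps):
        rep_seed = int(np.random.SeedSequence([master_seed, r]).generate_state(1)[0]
                       % (2 ** 31))
        rng = np.random.Generator(np.random.PCG64(rep_seed))
        tr, te = _stratified_split(labels_arr, train_frac, rng)
        acc = _fit_and_score([data[i] for i in tr], [data[i] for i in te],
                             classifier_spec, rep_seed, labels, confusion)
        accs.append(acc)
    return EvaluationReport(
        classifier=classifier_spec.model,
        accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        labels=labels,
        confusion=confusion.tolist(),
        master_seed=master_seed,
        train_frac=train_frac,
        reps=reps,
        config_digest=data_digest(data),
    )


def uniaxial_baseline(
    data: Sequence[MovementRecording],
    family: str = "dtw",
    train_frac: float = 0.8,
    reps: int = 100,
    master_seed: int = 0,
    metric: str = "euclidean",
    estimator: str = "mean",
    hyper: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Accuracy of each single-channel classifier (one per sensor/axis).

    Each channel is evaluated with the single-net degenerate form of the
    vector-input classifier under the same splits (same master seed), so
    rows are directly comparable; the best channel is flagged (first on
    ties).
    """
    if family not in ("dtw", "cnn"):
        raise ValueError("family must be 'dtw' or 'cnn'")
    spec = ClassifierSpec(model="dtw1" if family == "dtw" else "cnn1",
                          metric=metric, estimator=estimator, hyper=hyper)
    source_digest = data_digest(data)
    rows = []
    for g, m in data[0].channel_keys():
        restricted = [rec.restrict(g, m) for rec in data]
        rep = repeated_holdout(restricted, spec, train_frac=train_frac,
                               reps=reps, master_seed=master_seed)
        rows.append({"sensor": g, "axis": m, "family": family,
                     "mean_accuracy": rep.mean_accuracy,
                     "config_digest": source_digest})
    table = pd.DataFrame(rows)
    table["best"] = False
    table.loc[table["mean_accuracy"].idxmax(), "best"] = True
    return table


def random_baseline(n_classes: int) -> float:
    """Expected accuracy (%) of uniform random classification, to one
    decimal (e.g. 5.6% for an 18-class problem)."""
    if n_classes < 1:
        raise ValueError("need >= 1 class")
    return math.floor(100.0 / n_classes * 10.0 + 0.5) / 10.0


def fusion_vs_uniaxial_summary(
    fusion_reports: Sequence[EvaluationReport],
    uniaxial_table: pd.DataFrame,
) -> dict:
    """Worst-fusion vs best-uniaxial comparison (reporting only).

    Requires the fusion reports and the uniaxial table to come from the
    same ensemble (matching content digests).
    """
    digests = {r.config_digest for r in fusion_reports}
    digests |= set(uniaxial_table["config_digest"].unique())
    if len(digests) != 1:
        raise ValueError("reports come from different ensembles (digest mismatch)")
    worst = min(fusion_reports, key=lambda r: r.mean_accuracy)
    best_row = uniaxial_table.loc[uniaxial_table["mean_accuracy"].idxmax()]
    return {
        "min_fusion_accuracy": worst.mean_accuracy,
        "min_fusion_model": worst.classifier,
        "max_uniaxial_accuracy": float(best_row["mean_accuracy"]),
        "max_uniaxial_channel": (int(best_row["sensor"]), int(best_row["axis"])),
        "difference": worst.mean_accuracy - float(best_row["mean_accuracy"]),
    }
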