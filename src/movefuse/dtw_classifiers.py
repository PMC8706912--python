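"""Template estimation and the three DTW fusion classifiers.

DTW-1 (vector input): one vector DTW per channel per class; the ``M_G``
per-channel discrepancies are averaged into a fused score per class
(output-level fusion) and the least-discrepancy class wins.

DTW-2 (local matrix input): one matrix DTW per sensor per class; the ``G``
per-sensor discrepancies are averaged (hybrid input/output fusion).

DTW-3 (global matrix input): a single matrix DTW against each class's
global template (pure input-level fusion); no output fusion is needed.

For the DTW family the cuboid model adds nothing: frame-wise cost on a
cuboid equals column-wise cost on its stacked matrix, so a cuboid DTW
classifier is identical to DTW-3 and is deliberately not provided.

Class templates are element-wise central-tendency estimates (sample mean
by default) over a class's training instances after duration
normalization; the estimator is pluggable (median, trimmed/winsorized
mean, trimean) because a better central-tendency estimate does not
necessarily classify better, so the choice is left to the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import trim_mean
from scipy.stats.mstats import winsorize

from .signal_model import (
    MovementRecording,
    NormalizationSpec,
    build_input,
)
from .dtw import dtw_value

__all__ = [
    "ClassTemplate",
    "ESTIMATORS",
    "central_tendency",
    "fit_templates",
    "dtw1_classify",
    "dtw2_classify",
    "dtw3_classify",
    "dtw_classify",
]

ESTIMATORS = ("mean", "median", "trimmed_mean", "winsorized_mean", "trimean")


@dataclass
class ClassTemplate:
    """Per-class DTW reference in one input model's shape."""

    label: int
    model_tag: str
    payload: object   # VI: list of vectors; LMI: list of matrices; GMI: matrix
    estimator_tag: str


def central_tendency(stack: np.ndarray, estimator_tag: str, alpha: float = 0.2) -> np.ndarray:
    """Element-wise central tendency across axis 0 of a trial stack."""
    if estimator_tag == "mean":
        return stack.mean(axis=0)
    if estimator_tag == "median":
        return np.median(stack, axis=0)
    if estimator_tag == "trimmed_mean":
        return trim_mean(stack, alpha, axis=0)
    if estimator_tag == "winsorized_mean":
        return np.asarray(winsorize(stack, limits=(alpha, alpha), axis=0).mean(axis=0))
    if estimator_tag == "trimean":
        q1, q2, q3 = np.percentile(stack, [25, 50, 75], axis=0)
        return (q1 + 2 * q2 + q3) / 4.0
    raise ValueError(f"unknown estimator {estimator_tag!r}")


def _inputs_per_class(
    train: Sequence[MovementRecording], model_tag: str, spec: NormalizationSpec
) -> dict[int, list]:
    by_class: dict[int, list] = {}
    for rec in train:
        if rec.label is None:
            raise ValueError("training recordings must be labelled")
        fused = build_input(rec, model_tag, spec, normalize_vi_durations=True)
        by_class.setdefault(rec.label, []).append(fused.payload)
    return by_class


def fit_templates(
    train: Sequence[MovementRecording],
    model_tag: str,
    spec: NormalizationSpec,
    estimator_tag: str = "mean",
    alpha: float = 0.2,
    classes: Sequence[int] | None = None,
) -> dict[int, ClassTemplate]:
    """Estimate one reference template per class from a training set.

    VI channels are duration-normalized to their per-channel training-mean
    lengths before averaging (an element-wise mean is undefined otherwise).
    """
    by_class = _inputs_per_class(train, model_tag, spec)
    if classes is not None:
        missing = sorted(set(classes) - set(by_class))
        if missing:
            raise ValueError(f"classes absent from training set: {missing}")
    templates: dict[int, ClassTemplate] = {}
    for label in sorted(by_class):
        payloads = by_class[label]
        if model_tag in ("VI", "LMI"):
            n_units = len(payloads[0])
            agg = [
                central_tendency(np.stack([p[u] for p in payloads]), estimator_tag, alpha)
                for u in range(n_units)
            ]
        else:
            agg = central_tendency(np.stack(payloads), estimator_tag, alpha)
        templates[label] = ClassTemplate(label, model_tag, agg, estimator_tag)
    return templates


def _score_vector(
    rec: MovementRecording,
    templates: dict[int, ClassTemplate],
    spec: NormalizationSpec,
    model_tag: str,
    metric: str,
) -> tuple[np.ndarray, list[int]]:
    labels = sorted(templates)
    fused = build_input(rec, model_tag, spec, normalize_vi_durations=(model_tag == "VI"))
    scores = np.empty(len(labels))
    for idx, label in enumerate(labels):
        tpl = templates[label].payload
        if model_tag == "GMI":
            scores[idx] = dtw_value(fused.payload, tpl, metric)
        else:
            per_unit = [
                dtw_value(x, t, metric) for x, t in zip(fused.payload, tpl)
            ]
            scores[idx] = float(np.mean(per_unit))
    return scores, labels


def dtw1_classify(
    rec: MovementRecording,
    templates: dict[int, ClassTemplate],
    spec: NormalizationSpec,
    metric: str = "euclidean",
) -> tuple[int, np.ndarray]:
    """Vector-input classifier: M_G per-channel vector DTWs per class,
    discrepancies averaged over channels, least-discrepancy decision.

    Returns ``(predicted_label, fused_score_vector)`` with scores ordered
    by ascending class label; argmin ties break to the lowest label.
    """
    scores, labels = _score_vector(rec, templates, spec, "VI", metric)
    return labels[int(np.argmin(scores))], scores


def dtw2_classify(
    rec: MovementRecording,
    templates: dict[int, ClassTemplate],
    spec: NormalizationSpec,
    metric: str = "euclidean",
) -> tuple[int, np.ndarray]:
    """Local-matrix classifier: one matrix DTW per sensor per class,
    discrepancies averaged over the G sensors, least-discrepancy decision."""
    scores, labels = _score_vector(rec, templates, spec, "LMI", metric)
    return labels[int(np.argmin(scores))], scores


def dtw3_classify(
    rec: MovementRecording,
    templates: dict[int, ClassTemplate],
    spec: NormalizationSpec,
    metric: str = "euclidean",
) -> tuple[int, np.ndarray]:
    """Global-matrix classifier: a single matrix DTW against each class's
    global template; no output fusion."""
    scores, labels = _score_vector(rec, templates, spec, "GMI", metric)
    return labels[int(np.argmin(scores))], scores


_CLASSIFY = {"VI": dtw1_classify, "LMI": dtw2_classify, "GMI": dtw3_classify}


def dtw_classify(
    rec: MovementRecording,
    templates: dict[int, ClassTemplate],
    spec: NormalizationSpec,
    metric: str = "euclidean",
) -> tuple[int, np.ndarray]:
    """Dispatch on the templates' input model (DTW-1/2/3)."""
    tag = next(iter(templates.values())).model_tag
    if tag == "GCI":
        raise ValueError(
            "the cuboid model is equivalent to the global matrix model for "
            "DTW; use DTW-3 (GMI) instead"
        )
    return _CLASSIFY[tag](rec, templates, spec, metric)
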