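"""Subject-wise evaluation harnesses.

Cross-validation is *subject-wise*: fold k tests the subjects at ordinal
positions (2k-1, 2k, 2k+1) (1-based, stride 2) of the provided subject
list and trains on all the others, so no subject ever appears on both
sides of a fold.  Per-class accuracies are row-normalized confusion-matrix
percentages; the overall accuracy is the *macro* accuracy — the mean of
the row-normalized diagonal — not the pooled per-sample rate.  The
evaluation unit is the detected gait cycle (each cycle is classified
independently); per-sequence aggregation is available through the
pipeline's sequence-level decision.

Sequences flagged ``is_repetition`` (the same subject re-recorded) are
excluded from cross-validation and retained for cross-dataset training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .errors import ValidationError
from .io import CLASS_LABELS, SilhouetteSequence
from .errors import CycleDetectionError

logger = logging.getLogger(__name__)


@dataclass
class FoldSpec:
    """One subject-wise fold: three test subjects, the rest train."""

    k: int
    test_subjects: tuple[str, ...]
    train_subjects: tuple[str, ...]


@dataclass
class ConfusionMatrix:
    """Counts (rows = true class) and row-normalized percentages."""

    counts: np.ndarray
    row_percent: np.ndarray
    class_order: tuple[str, ...]


@dataclass
class CVResult:
    """Per-fold matrices, their mean/std and the macro overall accuracy."""

    fold_matrices: list[ConfusionMatrix]
    mean_matrix: np.ndarray
    std_matrix: np.ndarray
    overall_accuracy: float
    class_order: tuple[str, ...] = CLASS_LABELS


def make_subject_folds(subject_ids: Sequence[str], k: int = 10) -> list[FoldSpec]:
    """Stride-2 triple folds: fold k tests subjects (2k-1, 2k, 2k+1), 1-based.

    With 21 subjects and k=10 every subject appears in at least one test
    set and each training set holds 18 subjects.
    """
    ids = list(subject_ids)
    if len(ids) < 2 * k + 1:
        raise ValidationError(f"{len(ids)} subjects cannot support {k} stride-2 folds")
    folds = []
    for fold in range(1, k + 1):
        i = 2 * fold - 1  # 1-based position of the first test subject
        test = tuple(ids[i - 1 : i + 2])
        train = tuple(s for s in ids if s not in test)
        assert not set(test) & set(train)
        folds.append(FoldSpec(k=fold, test_subjects=test, train_subjects=train))
    return folds


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    class_order: Sequence[str] = CLASS_LABELS,
) -> ConfusionMatrix:
    if len(true_labels) != len(predicted_labels):
        raise ValidationError("label lists must have equal length")
    unknown = set(true_labels) | set(predicted_labels) - set(class_order)
    unknown -= set(class_order)
    if unknown:
        raise ValidationError(f"labels outside class order: {sorted(unknown)}")
    counts = _sk_confusion(true_labels, predicted_labels, labels=list(class_order))
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    for i, s in enumerate(row_sums.ravel()):
        if s == 0:
            logger.warning("no samples of class %r: percent row set to 0", class_order[i])
    return ConfusionMatrix(counts=counts, row_percent=pct, class_order=tuple(class_order))


def overall_accuracy(cm: ConfusionMatrix) -> float:
    """Macro accuracy: mean of the row-normalized diagonal, in percent.

    Classes absent from the test set are averaged out (with a warning)
    rather than dragging the mean to zero.
    """
    present = cm.counts.sum(axis=1) > 0
    if not present.any():
        return 0.0
    if not present.all():
        missing = [c for c, p in zip(cm.class_order, present) if not p]
        logger.warning("macro accuracy averaged over present classes only; missing %s", missing)
    return float(np.diag(cm.row_percent)[present].mean())


def _collect_cycle_predictions(
    pipeline, sequences: Sequence[SilhouetteSequence]
) -> tuple[list[str], list[str], int]:
    """Per-cycle (true, predicted) labels; sequences with no detectable
    cycle are skipped with a warning."""
    y_true, y_pred = [], []
    skipped = 0
    for seq in sequences:
        try:
            per_cycle, _ = pipeline.classify(seq)
        except CycleDetectionError:
            skipped += 1
            logger.warning(
                "no gait cycle detected in test sequence %s/%s; skipped",
                seq.subject_id, seq.class_label,
            )
            continue
        for cp in per_cycle:
            y_true.append(seq.class_label)
            y_pred.append(cp.decision)
    return y_true, y_pred, skipped


def cross_validate(
    sequences: Sequence[SilhouetteSequence],
    pipeline_factory: Callable[[int], object],
    folds: list[FoldSpec],
    class_order: Sequence[str] = CLASS_LABELS,
) -> CVResult:
    """Subject-wise cross-validation of the full two-stage pipeline.

    ``pipeline_factory(fold_index)`` must return a fresh unfitted
    pipeline.  Repetition sequences are excluded.  Both training stages
    see only the fold's training subjects.
    """
    sequences = [s for s in sequences if not s.is_repetition]
    subjects = {s.subject_id for s in sequences}
    matrices = []
    for fold in folds:
        missing = (set(fold.train_subjects) | set(fold.test_subjects)) - subjects
        if missing:
            raise ValidationError(f"fold {fold.k}: subjects missing from data: {sorted(missing)}")
        assert not set(fold.train_subjects) & set(fold.test_subjects)
        train = [s for s in sequences if s.subject_id in fold.train_subjects]
        test = [s for s in sequences if s.subject_id in fold.test_subjects]
        pipe = pipeline_factory(fold.k)
        pipe.fit(train)
        y_true, y_pred, _ = _collect_cycle_predictions(pipe, test)
        matrices.append(confusion_matrix(y_true, y_pred, class_order))
    stack = np.stack([m.row_percent for m in matrices])
    mean_matrix = stack.mean(axis=0)
    std_matrix = stack.std(axis=0, ddof=0)
    acc = float(np.diag(mean_matrix).mean())
    return CVResult(
        fold_matrices=matrices,
        mean_matrix=mean_matrix,
        std_matrix=std_matrix,
        overall_accuracy=acc,
        class_order=tuple(class_order),
    )


def cross_dataset_eval(
    train_sequences: Sequence[SilhouetteSequence],
    test_sequences: Sequence[SilhouetteSequence],
    pipeline_factory: Callable[[], object],
    class_order: Sequence[str] = CLASS_LABELS,
) -> tuple[ConfusionMatrix, float]:
    """Train once on one dataset, evaluate on another.

    Subject namespaces must be disjoint (identical train/test sets are a
    leakage error).  Repetition sequences are *included* in training.
    Returns the confusion matrix and the macro accuracy.
    """
    train_ids = {s.subject_id for s in train_sequences}
    test_ids = {s.subject_id for s in test_sequences}
    overlap = train_ids & test_ids
    if overlap:
        raise ValidationError(
            f"train/test subject namespaces overlap: {sorted(overlap)}; "
            "rename subjects to make the datasets disjoint"
        )
    pipe = pipeline_factory()
    pipe.fit(list(train_sequences))
    y_true, y_pred, _ = _collect_cycle_predictions(pipe, test_sequences)
    cm = confusion_matrix(y_true, y_pred, class_order)
    return cm, overall_accuracy(cm)
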