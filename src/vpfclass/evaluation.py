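"""Family-stratified cross-validation and classification metrics.

The unit of splitting is the protein family, stratified by functional
category: training uses every member sequence of the training families while
testing scores a single randomly chosen sequence per held-out family.
Splitting at sequence level instead would leak intra-family homology between
train and test.  Curves and areas are computed with scikit-learn
(``roc_curve`` / ``precision_recall_curve``); the precision-recall area uses
average-precision step summation rather than trapezoids, whose interpolation
is optimistic for PRC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve,
)

from ._errors import ValidationError
from .classifier import Classifier, ClassifierConfig, build_classifier
from .classifier import predict_proba as _predict_proba
from .classifier import train as _train
from .io import EmbeddingMatrix, FamilyTable

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    """Assignment of families to folds plus the chosen test sequence each."""

    k: int
    family_to_fold: dict[str, int]
    test_protein: dict[str, str]  # family -> the single sequence scored
    seed: int

    def fold_families(self, fold: int) -> list[str]:
        return sorted(f for f, i in self.family_to_fold.items() if i == fold)


def family_stratified_kfold(
    family_table: FamilyTable, k: int = 5, seed: int = 0
) -> FoldSplit:
    """Partition labeled families into ``k`` folds, stratified by category.

    Within each category families are shuffled under the seed and dealt
    round-robin, so per-category fold counts differ by at most one.  Every
    family also gets one uniformly chosen test sequence, fixed here so the
    choice is independent of downstream iteration order.
    """
    if k < 2:
        raise ValidationError(f"k must be >= 2, got {k}")
    by_category = family_table.families_by_category()
    unlabeled = set(family_table.families()) - set(family_table.labeled_families())
    if unlabeled:
        raise ValidationError(
            f"{len(unlabeled)} families are unlabeled (e.g. {sorted(unlabeled)[:3]})"
        )
    for cat, fams in by_category.items():
        if len(fams) < k:
            raise ValidationError(
                f"category {cat!r} has only {len(fams)} families, fewer than k={k}"
            )
    rng = np.random.default_rng(seed)
    family_to_fold: dict[str, int] = {}
    for cat in sorted(by_category):
        fams = list(by_category[cat])
        rng.shuffle(fams)
        for i, fam in enumerate(fams):
            family_to_fold[fam] = i % k
    all_fams = sorted(family_to_fold)
    test_protein = select_test_sequences(family_table, all_fams, seed=seed)
    return FoldSplit(k, family_to_fold, test_protein, seed)


def select_test_sequences(
    family_table: FamilyTable, test_families: Sequence[str], seed: int = 0
) -> dict[str, str]:
    """Choose one member uniformly at random per family, reproducibly."""
    rng = np.random.default_rng(seed)
    chosen: dict[str, str] = {}
    for fam in sorted(test_families):
        members = family_table.members(fam)  # raises on empty family
        chosen[fam] = members[rng.integers(len(members))]
    return chosen


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryCurves:
    fpr: np.ndarray
    tpr: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auroc: float
    auprc: float


def binary_curves(scores, binary_labels) -> BinaryCurves:
    """ROC and PRC over all distinct score thresholds, with their areas.

    AUROC is trapezoidal over the ROC; AUPRC is the precision-weighted
    recall-step sum (average precision).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(binary_labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D arrays")
    if labels.min() == labels.max():
        raise ValidationError("need at least one positive and one negative label")
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    return BinaryCurves(
        fpr, tpr, precision, recall,
        float(auc(fpr, tpr)),
        float(average_precision_score(labels, scores)),
    )


def f1_from_counts(tp: int, fp: int, fn: int) -> float:
    """F1 = 2·TP / (2·TP + FP + FN); defined as 0 when all counts are zero."""
    if tp < 0 or fp < 0 or fn < 0:
        raise ValidationError("counts must be non-negative")
    if tp + fp + fn == 0:
        logger.warning("F1 undefined for TP=FP=FN=0; returning 0.0")
        return 0.0
    return 2.0 * tp / (2.0 * tp + fp + fn)


def optimal_f1_threshold(scores, binary_labels) -> tuple[float, float]:
    """Threshold (rule: score >= t is positive) maximising F1.

    Searched over all distinct observed scores so the maximum is attained by
    at least one observed point; F1 ties break toward the larger threshold.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(binary_labels).astype(int)
    if labels.sum() == 0:
        raise ValidationError("need at least one positive label")
    order = np.argsort(-scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    cum_tp = np.cumsum(l_sorted)
    cum_fp = np.cumsum(1 - l_sorted)
    n_pos = int(labels.sum())
    # last index of each run of equal scores = counts at threshold s
    is_last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = cum_tp[is_last]
    fp = cum_fp[is_last]
    fn = n_pos - tp
    f1 = 2.0 * tp / (2.0 * tp + fp + fn)
    best = int(np.argmax(f1))  # scores descend, so first max = largest threshold
    return float(s_sorted[is_last][best]), float(f1[best])


def weighted_f1(per_category_f1, per_category_support) -> float:
    """Support-weighted arithmetic mean of per-category F1 scores."""
    f1 = np.asarray(per_category_f1, dtype=np.float64)
    support = np.asarray(per_category_support, dtype=np.float64)
    if f1.shape != support.shape:
        raise ValidationError("F1 and support vectors must have equal length")
    if np.any(support <= 0):
        raise ValidationError("supports must be positive")
    return float((f1 * support).sum() / support.sum())


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CategoryEval:
    category: str
    curves: BinaryCurves
    auroc: float
    auprc: float
    f1: float
    tp: int
    fp: int
    fn: int
    support: int
    optimal_threshold: float
    optimal_f1: float


@dataclass(frozen=True)
class EvalReport:
    """One fold's one-vs-rest evaluation across categories."""

    fold: int
    per_category: dict[str, CategoryEval]
    macro_auroc: float
    macro_auprc: float
    macro_f1: float
    weighted_f1: float
    n_test: int
    test_families: tuple[str, ...] = ()


@dataclass(frozen=True)
class CrossvalResult:
    reports: list[EvalReport]
    mean_auroc: float
    sd_auroc: float
    mean_auprc: float
    sd_auprc: float
    split: FoldSplit


def evaluate_predictions(
    probs: np.ndarray,
    true_categories: Sequence[str],
    category_names: Sequence[str],
    fold: int = 0,
    test_families: Sequence[str] = (),
) -> EvalReport:
    """One-vs-rest report from softmax probabilities and true labels.

    Per category the score is that category's probability column; TP/FP/FN
    come from argmax class assignment.
    """
    names = list(category_names)
    true_idx = np.array([names.index(c) for c in true_categories])
    pred_idx = probs.argmax(axis=1)
    per_category: dict[str, CategoryEval] = {}
    for j, cat in enumerate(names):
        y = (true_idx == j).astype(int)
        if y.min() == y.max():
            logger.warning(
                "fold %d: category %r has a single class in the test set; skipped",
                fold, cat,
            )
            continue
        curves = binary_curves(probs[:, j], y)
        tp = int(np.sum((pred_idx == j) & (true_idx == j)))
        fp = int(np.sum((pred_idx == j) & (true_idx != j)))
        fn = int(np.sum((pred_idx != j) & (true_idx == j)))
        thr, opt_f1 = optimal_f1_threshold(probs[:, j], y)
        per_category[cat] = CategoryEval(
            cat, curves, curves.auroc, curves.auprc,
            f1_from_counts(tp, fp, fn), tp, fp, fn, int(y.sum()), thr, opt_f1,
        )
    if not per_category:
        raise ValidationError("no category had both classes in the test set")
    cats = list(per_category.values())
    return EvalReport(
        fold=fold,
        per_category=per_category,
        macro_auroc=float(np.mean([c.auroc for c in cats])),
        macro_auprc=float(np.mean([c.auprc for c in cats])),
        macro_f1=float(np.mean([c.f1 for c in cats])),
        weighted_f1=weighted_f1([c.f1 for c in cats], [c.support for c in cats]),
        n_test=len(true_idx),
        test_families=tuple(test_families),
    )


def crossval_run(
    embeddings: EmbeddingMatrix,
    family_table: FamilyTable,
    config: ClassifierConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CrossvalResult:
    """Family-stratified k-fold cross-validation of the classifier.

    Per fold: train on every member sequence of the training families, score
    the single pre-selected sequence of each held-out family, and report
    one-vs-rest curves per category.
    """
    config = config or ClassifierConfig()
    if family_table.category_set is None:
        raise ValidationError("family table carries no category set")
    split = family_stratified_kfold(family_table, k=k, seed=seed)
    reports: list[EvalReport] = []
    for fold in range(k):
        test_fams = split.fold_families(fold)
        train_fams = [f for f in split.family_to_fold if split.family_to_fold[f] != fold]
        train_ids, train_labels = [], []
        for fam in sorted(train_fams):
            cat = family_table.category_of(fam)
            for pid in family_table.members(fam):
                if pid in embeddings:
                    train_ids.append(pid)
                    train_labels.append(cat)
        test_ids = [split.test_protein[f] for f in test_fams]
        test_labels = [family_table.category_of(f) for f in test_fams]
        fold_cfg = ClassifierConfig(
            hidden_dims=config.hidden_dims,
            dropout_rate=config.dropout_rate,
            n_epochs=config.n_epochs,
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            seed=(config.seed * k + fold) % (2**31),
            prepend_1024=config.prepend_1024,
        )
        clf = build_classifier(embeddings.dim, family_table.category_set, fold_cfg)
        _train(clf, embeddings.rows(train_ids), train_labels, fold_cfg)
        probs = _predict_proba(clf, embeddings.rows(test_ids))
        reports.append(
            evaluate_predictions(
                probs, test_labels, family_table.category_set.names,
                fold=fold, test_families=test_fams,
            )
        )
    aurocs = [r.macro_auroc for r in reports]
    auprcs = [r.macro_auprc for r in reports]
    return CrossvalResult(
        reports,
        float(np.mean(aurocs)), float(np.std(aurocs)),
        float(np.mean(auprcs)), float(np.std(auprcs)),
        split,
    )


# ---------------------------------------------------------------------------
# binary task assembly (e.g. phage virion protein benchmark)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabeledSet:
    """A named group of sequence ids with a train/test role."""

    class_name: str
    role: str  # "train" | "test"
    ids: tuple[str, ...]


@dataclass(frozen=True)
class BinaryTask:
    train_ids: tuple[str, ...]
    train_labels: tuple[int, ...]
    test_ids: tuple[str, ...]
    test_labels: tuple[int, ...]
    n_positive: int
    n_negative: int


def make_binary_task(
    labeled_sets: Sequence[LabeledSet], positive_class_names: Sequence[str]
) -> BinaryTask:
    """Merge class-labeled sets into one binary task, preserving roles.

    Sequences of positive classes are labeled 1, all others 0; an id present
    in both roles would leak train information into test and is an error.
    """
    positive = set(positive_class_names)
    if not any(s.class_name in positive for s in labeled_sets):
        raise ValidationError("no input set belongs to a positive class")
    for s in labeled_sets:
        if s.role not in ("train", "test"):
            raise ValidationError(f"set {s.class_name!r}: bad role {s.role!r}")
    train, test = {}, {}
    for s in labeled_sets:
        bucket = train if s.role == "train" else test
        for pid in s.ids:
            bucket[pid] = 1 if s.class_name in positive else 0
    overlap = set(train) & set(test)
    if overlap:
        raise ValidationError(
            f"{len(overlap)} ids appear in both train and test roles "
            f"(e.g. {sorted(overlap)[:3]})"
        )
    labels = list(train.values()) + list(test.values())
    n_pos = sum(labels)
    if n_pos == 0:
        raise ValidationError("positive classes contribute no sequences")
    logger.info("binary task: %d positives, %d negatives", n_pos, len(labels) - n_pos)
    return BinaryTask(
        tuple(train), tuple(train.values()),
        tuple(test), tuple(test.values()),
        n_pos, len(labels) - n_pos,
    )
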