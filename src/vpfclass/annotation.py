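"""Annotating unlabeled families: HMM ground truth, classifier calls, expansion.

Ground-truth categories for an external family database come from
profile-HMM hit tables against a reference whose categories are known: per
query, the best hit below the e-value cutoff supplies the label, skipping
unknown-function hits while a later qualifying hit has a known category.
Families the HMM search cannot label are then predicted from their centroid
embeddings, gated per category at the maximum-F1 probability threshold, and
the gain over HMM-only annotation is reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._errors import ValidationError
from .classifier import Classifier, predict_proba
from .embedspace import family_centroids
from .io import EmbeddingMatrix, FamilyTable, HmmHit, ProteinRecord

logger = logging.getLogger(__name__)

UNKNOWN_CATEGORY = "unknown function"


@dataclass(frozen=True)
class AnnotationCall:
    """A classifier-based category call for one family."""

    family_id: str
    category: str
    probability: float
    threshold: float
    accepted: bool
    source: str = "classifier"  # "hmm" | "classifier"

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"family {self.family_id!r}: probability {self.probability} "
                "outside [0, 1]"
            )
        if self.accepted and self.probability < self.threshold:
            raise ValidationError(
                f"family {self.family_id!r}: accepted below threshold"
            )


def assign_truth_labels(
    hits: list[HmmHit],
    target_categories: dict[str, str],
    evalue_cutoff: float = 1e-12,
    unknown_category: str = UNKNOWN_CATEGORY,
) -> dict[str, str]:
    """Per query family, the category of its lowest-e-value qualifying hit.

    Hits at or above the cutoff are ignored.  Unknown-function hits are
    skipped while any later qualifying hit carries a known category; if every
    qualifying hit is unknown-function the query is labeled unknown-function.
    Queries with no qualifying hit are left out (unlabeled).  E-value ties
    break by target family id, so the result is independent of row order.
    """
    if not evalue_cutoff > 0:
        raise ValidationError(f"evalue_cutoff must be > 0, got {evalue_cutoff}")
    by_query: dict[str, list[HmmHit]] = {}
    for hit in hits:
        if hit.target_family_id not in target_categories:
            raise ValidationError(
                f"hit target {hit.target_family_id!r} has no category"
            )
        if hit.evalue < evalue_cutoff:
            by_query.setdefault(hit.query_family_id, []).append(hit)
    labels: dict[str, str] = {}
    for query, qhits in by_query.items():
        qhits.sort(key=lambda h: (h.evalue, h.target_family_id))
        label = unknown_category
        for hit in qhits:
            cat = target_categories[hit.target_family_id]
            if cat != unknown_category:
                label = cat
                break
        labels[query] = label
    return labels


def predict_family_categories(
    classifier: Classifier,
    embeddings: EmbeddingMatrix,
    family_table: FamilyTable,
) -> dict[str, tuple[str, float]]:
    """Argmax category and probability per family, from centroid embeddings.

    The centroid is the family representation used throughout the
    embedding-space analysis, so prediction uses it too.
    """
    centroids = family_centroids(embeddings, family_table)
    mat = np.array([c.vector for c in centroids])
    probs = predict_proba(classifier, mat)
    names = classifier.categories.names
    out: dict[str, tuple[str, float]] = {}
    for c, p in zip(centroids, probs):
        j = int(p.argmax())
        out[c.family_id] = (names[j], float(p[j]))
    return out


def apply_thresholds(
    family_predictions: dict[str, tuple[str, float]],
    thresholds: dict[str, float],
) -> list[AnnotationCall]:
    """Gate each family prediction at its category's decision threshold.

    A call is accepted iff probability >= threshold; rejected calls are
    retained (accepted=False) so the accounting stays exhaustive.
    """
    calls: list[AnnotationCall] = []
    for fam in sorted(family_predictions):
        cat, prob = family_predictions[fam]
        if cat not in thresholds:
            raise ValidationError(f"no decision threshold for category {cat!r}")
        thr = thresholds[cat]
        calls.append(AnnotationCall(fam, cat, prob, thr, prob >= thr))
    return calls


@dataclass(frozen=True)
class ExpansionReport:
    """Annotation gain of threshold-gated classifier calls over HMM labels."""

    per_category: dict[str, tuple[int, int]]  # category -> (n_hmm, n_new)
    n_hmm: int
    n_new: int
    n_unannotated: int
    percent_increase: float
    conflicts: tuple[tuple[str, str, str], ...]  # (family, hmm_cat, clf_cat)


def expansion_report(
    hmm_labeled: dict[str, str], classifier_calls: list[AnnotationCall]
) -> ExpansionReport:
    """Count newly annotated families and the percentage gain over HMM labels.

    Every family lands in exactly one of: HMM-labeled, newly
    classifier-accepted, unannotated.  An accepted call for an HMM-labeled
    family with a different category is recorded as a conflict (the HMM label
    wins in the merged annotation), never as an error.
    """
    per_category: dict[str, list[int]] = {}
    for cat in hmm_labeled.values():
        per_category.setdefault(cat, [0, 0])[0] += 1
    conflicts: list[tuple[str, str, str]] = []
    n_new = n_unannotated = 0
    for call in classifier_calls:
        if call.family_id in hmm_labeled:
            if call.accepted and call.category != hmm_labeled[call.family_id]:
                conflicts.append(
                    (call.family_id, hmm_labeled[call.family_id], call.category)
                )
            continue
        if call.accepted:
            per_category.setdefault(call.category, [0, 0])[1] += 1
            n_new += 1
        else:
            n_unannotated += 1
    n_hmm = len(hmm_labeled)
    pct = 100.0 * n_new / n_hmm if n_hmm else float("nan")
    return ExpansionReport(
        {c: (v[0], v[1]) for c, v in sorted(per_category.items())},
        n_hmm, n_new, n_unannotated, pct, tuple(conflicts),
    )


def stratify_by_protein_length(
    calls: list[AnnotationCall],
    family_table: FamilyTable,
    records: list[ProteinRecord],
    split_length: float = 100.0,
) -> tuple[list[AnnotationCall], list[AnnotationCall]]:
    """Split calls by mean member protein length (<= split vs > split).

    Separates, e.g., short excisionase-like families from longer
    integrase/recombinase-like families within one predicted category.
    """
    if not split_length > 0:
        raise ValidationError(f"split_length must be > 0, got {split_length}")
    lengths = {r.protein_id: len(r.sequence) for r in records}
    short, long_ = [], []
    for call in calls:
        members = family_table.members(call.family_id)
        mls = [lengths[p] for p in members if p in lengths]
        if not mls:
            raise ValidationError(
                f"family {call.family_id!r} has no sequences with known length"
            )
        (short if np.mean(mls) <= split_length else long_).append(call)
    return short, long_
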