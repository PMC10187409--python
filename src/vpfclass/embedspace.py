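"""Structure of the pooled-embedding space.

Families are represented by the centroid (column mean) of their member
embeddings, and similarity at every level — sequence-sequence inside a
family, family-family inside and between categories — is cosine similarity.
The category-category similarity matrix is bipartitioned with spectral
clustering, and random two-group splits of the categories provide the
baseline that shows the spectral split is not an artefact of having only
two classes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import SpectralClustering

from ._errors import ValidationError
from .io import CategorySet, EmbeddingMatrix, FamilyTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyCentroid:
    family_id: str
    vector: np.ndarray
    n_members: int


@dataclass(frozen=True)
class CategorySimilarityMatrix:
    """Mean family-family cosine similarity within and between categories.

    Off-diagonal (A, B): mean over all cross pairs of family centroids.
    Diagonal (A, A): mean over unordered within-category pairs, excluding
    self-pairs (self-similarity of 1 would inflate it); NaN when a category
    has fewer than 2 families.
    """

    categories: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.categories),) * 2:
            raise ValidationError("matrix shape does not match category count")
        if not np.allclose(m, m.T, atol=1e-12, equal_nan=True):
            raise ValidationError("category similarity matrix must be symmetric")


def cosine_similarity(u, v) -> float:
    """dot(u, v) / (||u|| ||v||); both vectors must be nonzero."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValidationError("vectors must have the same dimension")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValidationError("cosine similarity undefined for the zero vector")
    return float(u @ v / (nu * nv))


def family_centroids(
    embeddings: EmbeddingMatrix, family_table: FamilyTable
) -> list[FamilyCentroid]:
    """Per-family column mean of member embedding rows."""
    out: list[FamilyCentroid] = []
    missing: list[str] = []
    for fam in family_table.families():
        members = [p for p in family_table.members(fam) if p in embeddings]
        if not members:
            missing.append(fam)
            continue
        out.append(
            FamilyCentroid(fam, embeddings.rows(members).mean(axis=0), len(members))
        )
    if missing:
        raise ValidationError(
            f"{len(missing)} families have no embedded members: {missing[:5]}"
        )
    return out


def _unit_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValidationError("cosine similarity undefined for the zero vector")
    return x / norms


def intra_family_similarity(
    embeddings: EmbeddingMatrix, family_table: FamilyTable
) -> dict[str, float]:
    """Mean pairwise member-member cosine per family with >= 2 members.

    Singleton families have no pairs and are skipped with a log note.
    """
    result: dict[str, float] = {}
    n_single = 0
    for fam in family_table.families():
        members = [p for p in family_table.members(fam) if p in embeddings]
        if len(members) < 2:
            n_single += 1
            continue
        unit = _unit_rows(embeddings.rows(members))
        gram = unit @ unit.T
        iu = np.triu_indices(len(members), k=1)
        result[fam] = float(gram[iu].mean())
    if n_single:
        logger.info("skipped %d singleton families (no pairs)", n_single)
    return result


def exclude_near_duplicate_families(
    per_family_similarities: dict[str, float], cutoff: float = 0.999
) -> dict[str, float]:
    """Drop families whose mean pairwise similarity exceeds ``cutoff``.

    Undeduplicated source databases contain families made entirely of
    duplicate sequences; their similarity of ~1 would distort summary
    statistics.  Exclusion applies only to the summary pool, never to other
    analyses.  The comparison is strictly greater-than.
    """
    if not 0 < cutoff <= 1:
        raise ValidationError(f"cutoff must be in (0, 1], got {cutoff}")
    kept = {f: s for f, s in per_family_similarities.items() if s <= cutoff}
    n_dropped = len(per_family_similarities) - len(kept)
    if n_dropped:
        logger.info("excluded %d near-duplicate families (> %g)", n_dropped, cutoff)
    return kept


def category_similarity_matrix(
    centroids: list[FamilyCentroid], family_table: FamilyTable
) -> CategorySimilarityMatrix:
    if len(family_table.families_by_category()) < 2:
        raise ValidationError("need at least 2 categories")
    by_cat = family_table.families_by_category()
    cats = tuple(sorted(by_cat))
    cent = {c.family_id: c.vector for c in centroids}
    unit_by_cat = {}
    for cat, fams in by_cat.items():
        try:
            unit_by_cat[cat] = _unit_rows(np.array([cent[f] for f in fams]))
        except KeyError as exc:
            raise ValidationError(f"no centroid for family {exc.args[0]!r}") from None
    m = np.full((len(cats), len(cats)), np.nan)
    for i, a in enumerate(cats):
        ua = unit_by_cat[a]
        if ua.shape[0] >= 2:
            gram = ua @ ua.T
            iu = np.triu_indices(ua.shape[0], k=1)
            m[i, i] = gram[iu].mean()
        else:
            logger.warning("category %r has < 2 families; diagonal undefined", a)
        for j in range(i + 1, len(cats)):
            cross = ua @ unit_by_cat[cats[j]].T
            m[i, j] = m[j, i] = cross.mean()
    return CategorySimilarityMatrix(cats, m)


def spectral_bipartition(
    category_matrix: CategorySimilarityMatrix, seed: int = 0
) -> dict[str, int]:
    """Two-group labeling of categories from spectral clustering (n=2).

    The similarity matrix serves directly as the affinity; if any entry is
    negative the whole matrix is mapped [-1, 1] -> [0, 1] first.  Undefined
    diagonal entries become 1 (a category is maximally similar to itself).
    A constant matrix carries no structure: it is flagged and an arbitrary
    seeded split returned with a warning.
    """
    cats = category_matrix.categories
    if len(cats) < 2:
        raise ValidationError("need at least 2 categories to bipartition")
    if len(cats) == 2:
        return {cats[0]: 0, cats[1]: 1}
    affinity = category_matrix.matrix.copy()
    np.fill_diagonal(affinity, np.where(np.isnan(np.diag(affinity)), 1.0, np.diag(affinity)))
    if np.isnan(affinity).any():
        raise ValidationError("affinity matrix contains undefined off-diagonals")
    if affinity.min() < 0:
        affinity = (affinity + 1.0) / 2.0
    off = affinity[~np.eye(len(cats), dtype=bool)]
    if np.ptp(off) < 1e-12:
        logger.warning("degenerate (constant) similarity matrix; arbitrary split")
        rng = np.random.default_rng(seed)
        labels = np.zeros(len(cats), dtype=int)
        labels[rng.choice(len(cats), size=len(cats) // 2, replace=False)] = 1
        return dict(zip(cats, labels.tolist()))
    sc = SpectralClustering(
        n_clusters=2, affinity="precomputed", random_state=seed, assign_labels="kmeans"
    )
    labels = sc.fit_predict(affinity)
    if labels.min() == labels.max():  # pragma: no cover - kmeans guards against this
        raise ValidationError("spectral clustering produced an empty group")
    return dict(zip(cats, labels.tolist()))


def random_category_bipartitions(
    categories, n_splits: int = 10, seed: int = 0
) -> list[dict[str, int]]:
    """Uniform random two-group splits with both groups non-empty."""
    cats = list(categories)
    if len(cats) < 2:
        raise ValidationError("need at least 2 categories")
    if n_splits < 1:
        raise ValidationError("n_splits must be >= 1")
    rng = np.random.default_rng(seed)
    splits: list[dict[str, int]] = []
    while len(splits) < n_splits:
        labels = rng.integers(0, 2, size=len(cats))
        if labels.min() == labels.max():  # rejection keeps the law uniform
            continue
        splits.append(dict(zip(cats, labels.tolist())))
    return splits


def relabel_families_by_partition(
    family_table: FamilyTable,
    partition: dict[str, int],
    group_names: tuple[str, str] = ("cluster1", "cluster2"),
) -> FamilyTable:
    """Replace each family's category by its partition group name.

    The result is a two-category table the classifier and evaluation
    machinery consume unchanged (the binary cluster-classification setup).
    """
    new_cats = CategorySet(group_names)
    fam_to_cat: dict[str, str] = {}
    for fam, cat in family_table.family_to_category.items():
        if cat not in partition:
            raise ValidationError(f"category {cat!r} missing from the partition")
        fam_to_cat[fam] = group_names[partition[cat]]
    return FamilyTable(dict(family_table.protein_to_family), fam_to_cat, new_cats)


def normalized_cut(affinity: np.ndarray, labels: np.ndarray) -> float:
    """Normalized-cut objective of a two-group labeling of an affinity matrix.

    cut(A,B)·(1/vol(A) + 1/vol(B)); used as a reference objective when
    checking spectral bipartitions on small category sets.
    """
    a = labels == 0
    b = ~a
    if not a.any() or not b.any():
        raise ValidationError("both groups must be non-empty")
    w = affinity.copy()
    np.fill_diagonal(w, 0.0)
    cut = w[np.ix_(a, b)].sum()
    vol_a, vol_b = w[a].sum(), w[b].sum()
    if vol_a == 0 or vol_b == 0:
        return np.inf
    return float(cut / vol_a + cut / vol_b)


def min_ncut_bipartition(affinity: np.ndarray) -> np.ndarray:
    """Exhaustive minimum-normalized-cut bipartition (small n only)."""
    n = affinity.shape[0]
    if n > 20:
        raise ValidationError("exhaustive search is limited to n <= 20")
    best, best_labels = np.inf, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + bits)
        if labels.max() == 0:
            continue
        val = normalized_cut(affinity, labels)
        if val < best:
            best, best_labels = val, labels
    return best_labels
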