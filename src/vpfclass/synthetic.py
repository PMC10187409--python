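"""Self-contained synthetic fixtures with planted structure.

Embeddings are drawn from a three-level spherical-Gaussian hierarchy —
category mean -> family mean -> sequence — so category separability, family
coherence and (optionally) a two-block category structure are all planted
quantities that downstream analyses must recover.  Sequence fixtures plant
family-correlated residue composition instead, so the context-free
:class:`~vpfclass.embedding.LookupEmbedder` produces family-clustered pooled
vectors from raw FASTA.  HMM hit-table fixtures plant a known truth,
including unknown-function decoy best hits that force the label-skipping
rule.  Nothing here attempts realistic protein evolution or HMM score
distributions; see docs/methods.md for what that implies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._errors import ValidationError
from .annotation import UNKNOWN_CATEGORY
from .io import (
    CANONICAL_RESIDUES,
    CategorySet,
    EmbeddingMatrix,
    FamilyTable,
    HmmHit,
    ProteinRecord,
)


@dataclass(frozen=True)
class BlockStructure:
    """Grouping of categories into two blocks of correlated means.

    ``within_correlation`` is the cosine between category-mean directions in
    the same block; between-block directions are orthogonal.
    """

    block_sizes: tuple[int, int] = (4, 5)
    within_correlation: float = 0.9

    def __post_init__(self) -> None:
        if min(self.block_sizes) < 1:
            raise ValidationError("both blocks must contain >= 1 category")
        if not 0.0 <= self.within_correlation < 1.0:
            raise ValidationError("within_correlation must be in [0, 1)")


@dataclass(frozen=True)
class SyntheticConfig:
    """Shape and geometry of a planted fixture.

    ``category_separation`` is the distance between (same-block-free)
    category means in units of ``sequence_noise_sd``.  ``family_spread`` and
    ``sequence_noise_sd`` are per-coordinate standard deviations; note the
    offset *norm* concentrates near sd·sqrt(dim), so the default spread of
    0.25 keeps held-out family displacement (norm ~2 at dim 64) well below
    the planted separation rather than comparable to it.
    """

    n_categories: int = 9
    families_per_category: int = 10
    sequences_per_family: int = 10
    dim: int = 64
    category_separation: float = 8.0
    family_spread: float = 0.25
    sequence_noise_sd: float = 1.0
    block_structure: BlockStructure | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_categories, self.families_per_category,
               self.sequences_per_family, self.dim) < 1:
            raise ValidationError("all counts must be positive")
        if self.category_separation < 0 or self.family_spread < 0:
            raise ValidationError("separations must be non-negative")
        if not self.sequence_noise_sd >= 0:
            raise ValidationError("sequence_noise_sd must be non-negative")
        if self.block_structure is not None and sum(
            self.block_structure.block_sizes
        ) != self.n_categories:
            raise ValidationError("block sizes must sum to n_categories")

    def category_names(self) -> tuple[str, ...]:
        return tuple(f"cat{i + 1:02d}" for i in range(self.n_categories))


def default_config(seed: int = 0) -> SyntheticConfig:
    """The standard well-separated fixture: 9 categories x 10 families x 10
    sequences in 64 dimensions at separation 8."""
    return SyntheticConfig(seed=seed)


def block_config(seed: int = 0) -> SyntheticConfig:
    """The two-block fixture (4+5 categories) for the spectral analyses.

    Blocks are far apart (separation 12) but same-block category means share
    90% of their direction, leaving them deliberately confusable — the
    regime in which a block-aligned binary split is easy while an arbitrary
    one is not.
    """
    return SyntheticConfig(
        category_separation=12.0,
        block_structure=BlockStructure((4, 5), 0.9),
        seed=seed,
    )


def _category_means(config: SyntheticConfig) -> np.ndarray:
    """Place category means on orthonormal directions at the planted geometry."""
    n, d = config.n_categories, config.dim
    scale = config.category_separation * config.sequence_noise_sd / np.sqrt(2.0)
    if config.block_structure is None:
        if d < n:
            raise ValidationError(
                f"dim {d} too small to place {n} means at the requested "
                "separation (need dim >= n_categories)"
            )
        means = np.zeros((n, d))
        means[np.arange(n), np.arange(n)] = scale
        return means
    if d < n + 2:
        raise ValidationError(
            f"dim {d} too small for {n} categories in two blocks "
            "(need dim >= n_categories + 2)"
        )
    rho = config.block_structure.within_correlation
    sizes = config.block_structure.block_sizes
    means = np.zeros((n, d))
    # axes 0-1: block directions; axes 2..n+1: per-category unique directions
    block_of = np.repeat([0, 1], sizes)
    for i in range(n):
        means[i, block_of[i]] = scale * np.sqrt(rho)
        means[i, 2 + i] = scale * np.sqrt(1.0 - rho)
    return means


def planted_blocks(config: SyntheticConfig) -> dict[str, int]:
    """Category -> block index mapping of the planted block structure."""
    if config.block_structure is None:
        raise ValidationError("config has no block structure")
    block_of = np.repeat([0, 1], config.block_structure.block_sizes)
    return dict(zip(config.category_names(), block_of.tolist()))


def generate_embedding_fixture(
    config: SyntheticConfig,
) -> tuple[FamilyTable, EmbeddingMatrix]:
    """Draw a labeled family table and embedding matrix from the hierarchy.

    sequence = category mean + family offset (sd ``family_spread``)
    + noise (sd ``sequence_noise_sd``), all spherical Gaussians.
    """
    rng = np.random.default_rng(config.seed)
    means = _category_means(config)
    cats = config.category_names()
    ids: list[str] = []
    rows: list[np.ndarray] = []
    protein_to_family: dict[str, str] = {}
    family_to_category: dict[str, str] = {}
    for ci, cat in enumerate(cats):
        for fi in range(config.families_per_category):
            fam = f"{cat}_fam{fi + 1:02d}"
            family_to_category[fam] = cat
            fam_mean = means[ci] + config.family_spread * rng.standard_normal(config.dim)
            for si in range(config.sequences_per_family):
                pid = f"{fam}_p{si + 1:02d}"
                ids.append(pid)
                rows.append(
                    fam_mean
                    + config.sequence_noise_sd * rng.standard_normal(config.dim)
                )
                protein_to_family[pid] = fam
    table = FamilyTable(protein_to_family, family_to_category, CategorySet(cats))
    return table, EmbeddingMatrix(ids, np.array(rows), f"synthetic-s{config.seed}")


def generate_sequence_fixture(
    config: SyntheticConfig,
    length_range: tuple[int, int] = (60, 200),
    n_overlength: int = 2,
    overlength: int = 6000,
) -> tuple[list[ProteinRecord], FamilyTable]:
    """Sample FASTA records whose residue composition tracks the family.

    Each category gets a sparse base residue profile; each family perturbs
    it.  A few records are emitted over the embedder's truncation limit so
    the truncation path is exercised on real input.
    """
    if length_range[0] < 1 or length_range[1] < length_range[0]:
        raise ValidationError(f"bad length_range {length_range}")
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(CANONICAL_RESIDUES))
    cats = config.category_names()
    records: list[ProteinRecord] = []
    protein_to_family: dict[str, str] = {}
    family_to_category: dict[str, str] = {}
    emitted = 0
    for cat in cats:
        base = rng.dirichlet(np.full(len(alphabet), 0.3))
        for fi in range(config.families_per_category):
            fam = f"{cat}_fam{fi + 1:02d}"
            family_to_category[fam] = cat
            profile = 0.7 * base + 0.3 * rng.dirichlet(np.full(len(alphabet), 0.3))
            for si in range(config.sequences_per_family):
                pid = f"{fam}_p{si + 1:02d}"
                length = (
                    overlength
                    if emitted < n_overlength
                    else int(rng.integers(length_range[0], length_range[1] + 1))
                )
                emitted += 1
                seq = "".join(rng.choice(alphabet, size=length, p=profile))
                records.append(ProteinRecord(pid, seq, fam))
                protein_to_family[pid] = fam
    table = FamilyTable(protein_to_family, family_to_category, CategorySet(cats))
    return records, table


@dataclass(frozen=True)
class HmmFixture:
    """A planted hit table plus everything needed to check recovery."""

    hits: tuple[HmmHit, ...]
    target_categories: dict[str, str]  # reference family -> category
    planted_truth: dict[str, str]  # query family -> category (qualifying only)
    withheld: frozenset[str]  # families with no qualifying hit
    decoy_families: frozenset[str]  # families whose best hit is unknown-function


def generate_hmm_hits_fixture(
    family_table: FamilyTable,
    hold_out_fraction: float = 0.3,
    decoy_fraction: float = 0.3,
    evalue_cutoff: float = 1e-12,
    seed: int = 0,
) -> HmmFixture:
    """Emit a hit table recovering each labeled family's category.

    A ``hold_out_fraction`` subset of families is withheld: they get either
    no hits at all or only hits above the cutoff.  The holdout is stratified
    by category (largest-remainder quotas, exact total of
    ``round(fraction * n)``): HMM coverage in the fixture carries no
    category bias, and every category keeps labeled families.  Of the
    labeled remainder, a ``decoy_fraction`` subset additionally receives an
    unknown-function hit with a strictly lower e-value than the true hit, so
    correct recovery requires skipping unknown-function labels.
    """
    if not 0 <= hold_out_fraction <= 1 or not 0 <= decoy_fraction <= 1:
        raise ValidationError("fractions must be in [0, 1]")
    fams = family_table.labeled_families()
    if not fams:
        raise ValidationError("family table has no labeled families")
    rng = np.random.default_rng(seed)
    n_withheld = int(round(hold_out_fraction * len(fams)))
    by_cat = family_table.families_by_category()
    quota = {c: hold_out_fraction * len(fs) for c, fs in by_cat.items()}
    counts = {c: int(np.floor(q)) for c, q in quota.items()}
    short = n_withheld - sum(counts.values())
    for c in sorted(quota, key=lambda c: quota[c] - counts[c], reverse=True)[:short]:
        counts[c] += 1
    withheld: set[str] = set()
    for c in sorted(by_cat):
        take = min(counts[c], len(by_cat[c]))
        withheld |= set(rng.choice(by_cat[c], size=take, replace=False).tolist())
    labeled = [f for f in fams if f not in withheld]
    n_decoy = int(round(decoy_fraction * len(labeled)))
    decoys = set(rng.choice(labeled, size=n_decoy, replace=False).tolist()) if labeled else set()

    target_categories: dict[str, str] = {}
    hits: list[HmmHit] = []
    planted: dict[str, str] = {}

    def _ref(category: str, i: int) -> str:
        name = f"ref_{category.replace(' ', '_')}_{i:03d}"
        target_categories[name] = category
        return name

    for i, fam in enumerate(labeled):
        cat = family_table.category_of(fam)
        true_e = 10.0 ** rng.uniform(-30, np.log10(evalue_cutoff) - 1)
        hits.append(HmmHit(fam, _ref(cat, i), true_e))
        planted[fam] = cat
        if fam in decoys:
            decoy_e = true_e * 10.0 ** (-rng.uniform(1, 5))
            hits.append(HmmHit(fam, _ref(UNKNOWN_CATEGORY, i), decoy_e))
    for i, fam in enumerate(sorted(withheld)):
        if i % 2 == 0:  # half get a non-qualifying hit, half none at all
            cat = family_table.category_of(fam)
            weak_e = 10.0 ** rng.uniform(np.log10(evalue_cutoff) + 1, -3)
            hits.append(HmmHit(fam, _ref(cat, 10_000 + i), weak_e))
    order = rng.permutation(len(hits))  # row order carries no information
    return HmmFixture(
        tuple(hits[i] for i in order),
        target_categories,
        planted,
        frozenset(withheld),
        frozenset(decoys),
    )
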