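"""Domain types and file formats.

Sequences travel as FASTA, family/category tables and HMM hit tables as TSV
with a header row, and embedding matrices as a single HDF5 file holding an id
index plus one dense 2-D float array.  Category names are matched
case-sensitively after whitespace trimming: silent normalisation would hide
curation errors in hand-maintained annotation tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

from ._errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: residues with defined one-letter codes; ambiguity codes X/B/Z and the
#: rare U (selenocysteine) are tolerated in input sequences
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_RESIDUES = CANONICAL_RESIDUES + "XBZU"


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence, optionally tagged with its family."""

    protein_id: str
    sequence: str
    family_id: str | None = None

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(
                f"protein {self.protein_id!r}: sequence must have length >= 1"
            )


@dataclass(frozen=True)
class CategorySet:
    """Ordered functional-category names; order fixes classifier column order."""

    names: tuple[str, ...]
    unknown_name: str | None = None

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValidationError("category names must be unique")
        if self.unknown_name is not None and self.unknown_name not in self.names:
            raise ValidationError(
                f"unknown-function category {self.unknown_name!r} not in set"
            )

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ValidationError(f"unknown category {name!r}") from None

    def without(self, name: str) -> "CategorySet":
        """A copy with ``name`` removed (e.g. dropping 'unknown function')."""
        if name not in self.names:
            raise ValidationError(f"unknown category {name!r}")
        rest = tuple(n for n in self.names if n != name)
        unk = self.unknown_name if self.unknown_name != name else None
        return CategorySet(rest, unk)


@dataclass
class FamilyTable:
    """Protein -> family and family -> category mappings.

    ``family_to_category`` may be empty for an unlabeled set.  Member lists
    are kept sorted so construction is independent of input row order.
    """

    protein_to_family: dict[str, str]
    family_to_category: dict[str, str]
    category_set: CategorySet | None = None
    _members: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._members:
            members: dict[str, list[str]] = {}
            for pid, fam in self.protein_to_family.items():
                members.setdefault(fam, []).append(pid)
            self._members = {f: sorted(ms) for f, ms in members.items()}
        if self.category_set is not None:
            for fam, cat in self.family_to_category.items():
                if cat not in self.category_set:
                    raise ValidationError(
                        f"family {fam!r} has category {cat!r} not in the category set"
                    )

    # -- queries -----------------------------------------------------------
    def families(self) -> list[str]:
        fams = set(self._members) | set(self.family_to_category)
        return sorted(fams)

    def members(self, family_id: str) -> list[str]:
        try:
            return list(self._members[family_id])
        except KeyError:
            raise ValidationError(f"family {family_id!r} has no members") from None

    def category_of(self, family_id: str) -> str:
        try:
            return self.family_to_category[family_id]
        except KeyError:
            raise ValidationError(f"family {family_id!r} is unlabeled") from None

    def is_labeled(self, family_id: str) -> bool:
        return family_id in self.family_to_category

    def labeled_families(self) -> list[str]:
        return sorted(f for f in self._members if f in self.family_to_category)

    def families_by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for fam in self.labeled_families():
            out.setdefault(self.family_to_category[fam], []).append(fam)
        return {c: sorted(fs) for c, fs in out.items()}

    def restrict_to_families(self, family_ids) -> "FamilyTable":
        keep = set(family_ids)
        return FamilyTable(
            {p: f for p, f in self.protein_to_family.items() if f in keep},
            {f: c for f, c in self.family_to_category.items() if f in keep},
            self.category_set,
        )


@dataclass(frozen=True)
class HmmHit:
    """One profile-HMM search hit between a query and a target family."""

    query_family_id: str
    target_family_id: str
    evalue: float

    def __post_init__(self) -> None:
        if not self.evalue > 0:
            raise ValidationError(
                f"hit {self.query_family_id!r}->{self.target_family_id!r}: "
                f"e-value must be > 0, got {self.evalue!r}"
            )


@dataclass
class EmbeddingMatrix:
    """Fixed-dimension pooled vectors, one row per sequence id."""

    ids: list[str]
    values: np.ndarray
    embedder: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("embedding values must be a 2-D array")
        if len(self.ids) != self.values.shape[0]:
            raise ValidationError(
                f"{len(self.ids)} ids but {self.values.shape[0]} embedding rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("embedding ids must be unique")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValidationError("embedding matrix contains non-finite values")
        if self.values.shape[1] < 1:
            raise ValidationError("embedding dimension must be >= 1")
        self._index = {pid: i for i, pid in enumerate(self.ids)}

    @property
    def dim(self) -> int:
        return int(self.values.shape[1])

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def row(self, protein_id: str) -> np.ndarray:
        try:
            return self.values[self._index[protein_id]]
        except KeyError:
            raise ValidationError(f"no embedding for id {protein_id!r}") from None

    def rows(self, protein_ids) -> np.ndarray:
        idx = [self._index[p] for p in protein_ids]
        return self.values[idx]

    def subset(self, protein_ids) -> "EmbeddingMatrix":
        ids = list(protein_ids)
        return EmbeddingMatrix(ids, self.rows(ids), self.embedder)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file; the header token before the first whitespace is the id."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"FASTA entry {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, seq))
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.protein_id}\n")
            for i in range(0, len(rec.sequence), 80):
                fh.write(rec.sequence[i : i + 80] + "\n")


def read_family_table(path, category_set: CategorySet | None = None) -> FamilyTable:
    """Read a TSV of (protein_id, family_id[, category]) rows.

    The category column may be absent for unlabeled sets.  A protein mapped
    to two different families, or a family mapped to two different
    categories, is rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "family_id"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: expected columns protein_id, family_id; got {list(df.columns)}"
        )
    has_category = "category" in df.columns
    protein_to_family: dict[str, str] = {}
    family_to_category: dict[str, str] = {}
    for row in df.itertuples(index=False):
        pid, fam = str(row.protein_id).strip(), str(row.family_id).strip()
        if pid in protein_to_family and protein_to_family[pid] != fam:
            raise ValidationError(
                f"protein {pid!r} assigned to two families: "
                f"{protein_to_family[pid]!r} and {fam!r}"
            )
        protein_to_family[pid] = fam
        if has_category and not pd.isna(row.category):
            cat = str(row.category).strip()
            if category_set is not None and cat not in category_set:
                raise ValidationError(
                    f"family {fam!r}: category {cat!r} not in the category set "
                    "(matching is case-sensitive)"
                )
            if fam in family_to_category and family_to_category[fam] != cat:
                raise ValidationError(
                    f"family {fam!r} has conflicting categories "
                    f"{family_to_category[fam]!r} and {cat!r}"
                )
            family_to_category[fam] = cat
    return FamilyTable(protein_to_family, family_to_category, category_set)


def write_family_table(table: FamilyTable, path) -> None:
    rows = []
    for fam in table.families():
        cat = table.family_to_category.get(fam, "")
        for pid in table.members(fam):
            rows.append((pid, fam, cat))
    pd.DataFrame(rows, columns=["protein_id", "family_id", "category"]).to_csv(
        path, sep="\t", index=False
    )


def read_hmm_hits(path) -> list[HmmHit]:
    """Read a TSV of (query_family, target_family, evalue) hit rows."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"query_family", "target_family", "evalue"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: expected columns query_family, target_family, evalue; "
            f"got {list(df.columns)}"
        )
    hits: list[HmmHit] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            evalue = float(row.evalue)
        except (TypeError, ValueError):
            raise ParseError(
                f"{path}: row {i}: unparseable e-value {row.evalue!r}"
            ) from None
        if not evalue > 0:
            raise ParseError(f"{path}: row {i}: e-value must be > 0, got {evalue}")
        hits.append(HmmHit(str(row.query_family), str(row.target_family), evalue))
    return hits


def write_hmm_hits(hits, path) -> None:
    pd.DataFrame(
        [(h.query_family_id, h.target_family_id, h.evalue) for h in hits],
        columns=["query_family", "target_family", "evalue"],
    ).to_csv(path, sep="\t", index=False)


def write_embeddings(matrix: EmbeddingMatrix, path) -> None:
    """Write an embedding matrix to HDF5 (datasets 'ids', 'embeddings')."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset(
            "ids", data=np.array(matrix.ids, dtype=h5py.string_dtype("utf-8"))
        )
        fh.create_dataset("embeddings", data=matrix.values)
        fh.attrs["embedder"] = matrix.embedder


def read_embeddings(path) -> EmbeddingMatrix:
    """Read an embedding matrix written by :func:`write_embeddings`."""
    with h5py.File(path, "r") as fh:
        if "ids" not in fh or "embeddings" not in fh:
            raise ParseError(f"{path}: missing 'ids' or 'embeddings' dataset")
        ids = [x.decode() if isinstance(x, bytes) else str(x) for x in fh["ids"][()]]
        try:
            values = np.asarray(fh["embeddings"][()], dtype=np.float64)
        except (ValueError, TypeError):
            raise ParseError(
                f"{path}: embedding rows have inconsistent widths"
            ) from None
        embedder = str(fh.attrs.get("embedder", "unknown"))
    if values.ndim != 2:
        raise ParseError(f"{path}: embedding rows have inconsistent widths")
    return EmbeddingMatrix(ids, values, embedder)


def align_records_to_embeddings(
    records: list[ProteinRecord], matrix: EmbeddingMatrix
) -> tuple[list[ProteinRecord], EmbeddingMatrix]:
    """Intersect a sequence set with an embedding store on shared ids.

    Datasets assembled from heterogeneous sources rarely agree exactly, so
    ids present on only one side are reported and dropped rather than
    treated as an error.
    """
    rec_ids = {r.protein_id for r in records}
    emb_ids = set(matrix.ids)
    only_rec = rec_ids - emb_ids
    only_emb = emb_ids - rec_ids
    if only_rec:
        logger.warning(
            "%d sequences have no embedding and were dropped (e.g. %s)",
            len(only_rec), sorted(only_rec)[:3],
        )
    if only_emb:
        logger.warning(
            "%d embeddings have no sequence and were dropped (e.g. %s)",
            len(only_emb), sorted(only_emb)[:3],
        )
    shared = rec_ids & emb_ids
    kept = [r for r in records if r.protein_id in shared]
    return kept, matrix.subset([r.protein_id for r in kept])
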