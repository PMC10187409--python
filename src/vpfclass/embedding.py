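"""Sequence -> fixed-dimension pooled vectors.

A protein language model assigns each residue a d-dimensional vector; the
sequence representation is the arithmetic mean of those vectors (mean
pooling).  External PLM backends run out-of-process and deliver their output
through the HDF5 embedding store; the built-in :class:`LookupEmbedder` is a
deterministic context-free baseline — one fixed random vector per residue
letter — whose pooled vectors reflect residue composition, enough to exercise
every downstream stage without any deep-learning runtime.
"""

from __future__ import annotations

import logging
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from ._errors import ValidationError
from .io import CANONICAL_RESIDUES, EmbeddingMatrix, ProteinRecord

logger = logging.getLogger(__name__)

#: longest sequence embedded; longer sequences are truncated, matching the
#: input-length limit of large transformer PLMs
DEFAULT_MAX_LEN = 5096


@runtime_checkable
class Embedder(Protocol):
    """Contract: map an amino-acid string to per-residue d-vectors."""

    name: str
    dim: int

    def embed_residues(self, sequence: str) -> np.ndarray:
        """Return an array of shape (len(sequence), dim)."""
        ...


class LookupEmbedder:
    """Context-free per-letter embedder with a seeded random lookup table.

    Table entries are drawn from a standard normal: in moderate dimension the
    letter vectors are near-orthogonal, so pooled vectors separate sequences
    by residue composition.  Unknown letters (X, B, Z, U, or anything else)
    map to the all-zeros vector, which keeps the output dimension and the
    pooling arithmetic well defined.
    """

    def __init__(self, dim: int = 64, seed: int = 0):
        if dim < 1:
            raise ValidationError(f"embedding dimension must be >= 1, got {dim}")
        self.dim = int(dim)
        self.seed = int(seed)
        self.name = f"lookup-d{dim}-s{seed}"
        rng = np.random.default_rng(seed)
        self._table = {
            letter: rng.standard_normal(dim) for letter in CANONICAL_RESIDUES
        }
        self._zero = np.zeros(dim)

    def embed_residues(self, sequence: str) -> np.ndarray:
        if not sequence:
            raise ValidationError("cannot embed an empty sequence")
        return np.array([self._table.get(a, self._zero) for a in sequence])


def truncate_sequence(sequence: str, max_len: int = DEFAULT_MAX_LEN) -> str:
    """Return the first ``min(len, max_len)`` residues of ``sequence``."""
    if not sequence:
        raise ValidationError("cannot truncate an empty sequence")
    if max_len < 1:
        raise ValidationError(f"max_len must be >= 1, got {max_len}")
    return sequence[:max_len]


def mean_pool(residue_vectors: Sequence | np.ndarray) -> np.ndarray:
    """Element-wise arithmetic mean over per-residue vectors."""
    try:
        arr = np.asarray(residue_vectors, dtype=np.float64)
    except ValueError:
        raise ValidationError(
            "residue vectors must all have the same dimension"
        ) from None
    if arr.size == 0:
        raise ValidationError("mean_pool requires at least one residue vector")
    if arr.ndim != 2:
        raise ValidationError("residue vectors must all have the same dimension")
    return arr.mean(axis=0)


def embed_sequences(
    records: Sequence[ProteinRecord],
    embedder: Embedder,
    max_len: int = DEFAULT_MAX_LEN,
) -> EmbeddingMatrix:
    """Embed each record to a pooled vector; rows follow input order."""
    if not records:
        raise ValidationError("no records to embed")
    rows = np.empty((len(records), embedder.dim))
    n_truncated = 0
    for i, rec in enumerate(records):
        seq = truncate_sequence(rec.sequence, max_len)
        if len(seq) < len(rec.sequence):
            n_truncated += 1
        vectors = embedder.embed_residues(seq)
        if vectors.shape != (len(seq), embedder.dim):
            raise ValidationError(
                f"embedder {embedder.name!r} returned shape {vectors.shape} "
                f"for a sequence of length {len(seq)} (dim {embedder.dim})"
            )
        rows[i] = mean_pool(vectors)
    if n_truncated:
        logger.info("truncated %d sequences to %d residues", n_truncated, max_len)
    return EmbeddingMatrix([r.protein_id for r in records], rows, embedder.name)
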