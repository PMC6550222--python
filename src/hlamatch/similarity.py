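"""Continuous sequence similarity between two HLA proteins of one locus.

A substitution matrix turns two aligned protein sequences into a raw score
(sum of per-position substitution scores over the positions where neither
sequence has a gap).  The raw score is then cosine-normalized,

    s(x, y) = raw(x, y) / sqrt(raw(x, x) * raw(y, y)),

where every raw score in the quotient — including the self-scores — is
computed over the same position set, the positions that are non-gap in both
x and y.  By Cauchy–Schwarz on that shared support the normalized value lies
in [-1, 1] and self-similarity is exactly 1, which makes the two
matrix-based similarities (f1: BLOSUM50, f2: covariance-style matrix) and
the embedding similarity f3 commensurable features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Mapping

import numpy as np

from .hla_model import (
    HLAAllele,
    ProteinRecord,
    ResolutionError,
    SubstitutionMatrix,
    load_bundled_matrix,
)


class SimilarityError(ValueError):
    """Raised when a similarity is undefined for the given inputs."""


def raw_matrix_score(seq_x: str, seq_y: str, m: SubstitutionMatrix) -> float:
    """Sum of substitution scores over positions non-gap in both sequences.

    Positions with a gap in either sequence contribute nothing.  Raises if
    the aligned lengths differ or no non-gap position overlaps.
    """
    if len(seq_x) != len(seq_y):
        raise SimilarityError(
            f"aligned length mismatch: {len(seq_x)} vs {len(seq_y)}"
        )
    cx, cy = m.encode(seq_x), m.encode(seq_y)
    keep = (cx >= 0) & (cy >= 0)
    if not keep.any():
        raise SimilarityError("no overlapping non-gap positions; similarity undefined")
    return float(m.values[cx[keep], cy[keep]].sum())


def normalized_similarity(seq_x: str, seq_y: str, m: SubstitutionMatrix) -> float:
    """Cosine-style normalized substitution score in [-1, 1].

    All three raw scores (cross and both self) are evaluated on the shared
    non-gap support of the pair, so identical sequences score exactly 1.
    """
    if len(seq_x) != len(seq_y):
        raise SimilarityError(
            f"aligned length mismatch: {len(seq_x)} vs {len(seq_y)}"
        )
    cx, cy = m.encode(seq_x), m.encode(seq_y)
    keep = (cx >= 0) & (cy >= 0)
    if not keep.any():
        raise SimilarityError("no overlapping non-gap positions; similarity undefined")
    cx, cy = cx[keep], cy[keep]
    cross = float(m.values[cx, cy].sum())
    self_x = float(m.values[cx, cx].sum())
    self_y = float(m.values[cy, cy].sum())
    if self_x <= 0 or self_y <= 0:
        raise SimilarityError(
            f"non-positive self-score ({self_x}, {self_y}); "
            f"matrix {m.name} unsuitable for cosine normalization"
        )
    return cross / np.sqrt(self_x * self_y)


@dataclass
class SimilarityFunction:
    """A symmetric allele-level similarity for one locus.

    ``kind`` is one of ``f1`` (BLOSUM50 sequence similarity), ``f2``
    (covariance-matrix sequence similarity) or ``f3`` (binding-affinity
    embedding similarity).  Calls are cached per unordered allele pair.
    """

    kind: str
    locus: str
    _fn: Callable[[HLAAllele, HLAAllele], float]
    _cache: Dict[FrozenSet[HLAAllele], float] = field(default_factory=dict, repr=False)

    def __call__(self, x: HLAAllele, y: HLAAllele) -> float:
        key = frozenset((x, y))
        try:
            return self._cache[key]
        except KeyError:
            value = self._fn(x, y)
            self._cache[key] = value
            return value


def _matrix_similarity_function(
    kind: str,
    locus: str,
    sequence_store: Mapping[HLAAllele, ProteinRecord],
    matrix: SubstitutionMatrix,
) -> SimilarityFunction:
    def fn(x: HLAAllele, y: HLAAllele) -> float:
        for a in (x, y):
            if a not in sequence_store:
                raise ResolutionError(f"allele {a} has no sequence record")
            if a.locus != locus:
                raise SimilarityError(f"allele {a} is not at locus {locus}")
        return normalized_similarity(
            sequence_store[x].sequence, sequence_store[y].sequence, matrix
        )

    return SimilarityFunction(kind=kind, locus=locus, _fn=fn)


def make_f1(
    locus: str,
    sequence_store: Mapping[HLAAllele, ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
) -> SimilarityFunction:
    """BLOSUM50-based normalized sequence similarity for one locus."""
    return _matrix_similarity_function(
        "f1", locus, sequence_store, matrix or load_bundled_matrix("blosum50")
    )


def make_f2(
    locus: str,
    sequence_store: Mapping[HLAAllele, ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
) -> SimilarityFunction:
    """Covariance-style-matrix normalized sequence similarity for one locus.

    The bundled default matrix is a synthetic physicochemical covariance
    stand-in (see :func:`hlamatch.hla_model.load_bundled_matrix`); any
    symmetric matrix with positive self-scores may be supplied instead.
    """
    return _matrix_similarity_function(
        "f2", locus, sequence_store, matrix or load_bundled_matrix("pmbec_synthetic")
    )
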