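"""Binding-affinity embeddings of HLA proteins (the f3 representation).

A protein × peptide binding-affinity matrix (partially observed) is
factorized into rank-n protein vectors P and peptide vectors Q by
regularized alternating least squares on the observed entries:

    minimize  sum_observed (a_ij - p_i . q_j)^2 + lambda (||P||^2 + ||Q||^2)

Each protein vector is a fixed-dimension continuous representation of the
protein's peptide-binding behaviour; the f3 similarity between two proteins
is the cosine-normalized inner product of their vectors.  Proteins with no
affinity data are imputed by the same-locus embedded protein with the
highest BLOSUM50 sequence similarity.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .hla_model import (
    HLAAllele,
    ProteinRecord,
    ResolutionError,
    SubstitutionMatrix,
    load_bundled_matrix,
    parse_allele,
)
from .similarity import SimilarityError, SimilarityFunction, normalized_similarity

#: Conventional IC50 ceiling (nM) for the log-transform of binding affinities.
DEFAULT_MAX_IC50 = 50000.0


class EmbeddingError(ValueError):
    """Raised for invalid affinity data or factorization configuration."""


def transform_affinity(raw_value: float | np.ndarray, max_ic50: float = DEFAULT_MAX_IC50):
    """Map an IC50 value (nM) to the [0, 1] affinity scale.

    Uses the standard ``1 - log(ic50)/log(max_ic50)`` transform, clamped to
    [0, 1]; strong binders (low IC50) map near 1.  Raises on non-positive
    input.
    """
    arr = np.asarray(raw_value, dtype=float)
    if np.any(arr <= 0):
        raise EmbeddingError("IC50 values must be strictly positive")
    out = np.clip(1.0 - np.log(arr) / math.log(max_ic50), 0.0, 1.0)
    return float(out) if np.isscalar(raw_value) else out


@dataclass
class AffinityMatrix:
    """A partially observed protein × peptide affinity table.

    ``values[i, j]`` is meaningful only where ``observed[i, j]``; every
    retained protein row must have at least ``min_observed`` entries.
    """

    proteins: List[HLAAllele]
    peptides: List[str]
    values: np.ndarray
    observed: np.ndarray
    min_observed: int = 5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        shape = (len(self.proteins), len(self.peptides))
        if self.values.shape != shape or self.observed.shape != shape:
            raise EmbeddingError("affinity matrix shape/index mismatch")
        if not np.all(np.isfinite(self.values[self.observed])):
            raise EmbeddingError("observed affinity values must be finite")
        counts = self.observed.sum(axis=1)
        thin = [str(p) for p, c in zip(self.proteins, counts) if c < self.min_observed]
        if thin:
            raise EmbeddingError(
                f"protein rows with fewer than {self.min_observed} observed entries: {thin}"
            )

    @classmethod
    def from_long_table(
        cls,
        path: str | Path,
        transform: str = "none",
        min_observed: int = 5,
    ) -> "AffinityMatrix":
        """Read a long-format table with columns protein_allele, peptide_id, value.

        ``transform="ic50"`` applies the IC50 log-transform; ``"none"``
        passes values through (for pre-transformed inputs).
        """
        df = pd.read_csv(path, sep=None, engine="python")
        needed = {"protein_allele", "peptide_id", "value"}
        if not needed.issubset(df.columns):
            raise EmbeddingError(f"affinity table needs columns {sorted(needed)}")
        values = df["value"].to_numpy(dtype=float)
        if transform == "ic50":
            values = transform_affinity(values)
        elif transform != "none":
            raise EmbeddingError(f"unknown affinity transform {transform!r}")
        proteins = sorted({parse_allele(a) for a in df["protein_allele"]})
        peptides = sorted({str(p) for p in df["peptide_id"]})
        p_idx = {p: i for i, p in enumerate(proteins)}
        q_idx = {q: j for j, q in enumerate(peptides)}
        mat = np.zeros((len(proteins), len(peptides)))
        mask = np.zeros_like(mat, dtype=bool)
        for allele, pep, v in zip(df["protein_allele"], df["peptide_id"], values):
            i, j = p_idx[parse_allele(allele)], q_idx[str(pep)]
            mat[i, j] = v
            mask[i, j] = True
        return cls(proteins=proteins, peptides=peptides, values=mat, observed=mask,
                   min_observed=min_observed)

    def to_long_table(self, path: str | Path) -> None:
        rows = [
            {"protein_allele": p.name, "peptide_id": q, "value": self.values[i, j]}
            for i, p in enumerate(self.proteins)
            for j, q in enumerate(self.peptides)
            if self.observed[i, j]
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    def restrict_to_locus(self, locus: str) -> "AffinityMatrix":
        keep = [i for i, p in enumerate(self.proteins) if p.locus == locus]
        if not keep:
            raise EmbeddingError(f"no proteins at locus {locus} in affinity matrix")
        return AffinityMatrix(
            proteins=[self.proteins[i] for i in keep],
            peptides=list(self.peptides),
            values=self.values[keep],
            observed=self.observed[keep],
            min_observed=self.min_observed,
        )


@dataclass
class ProteinEmbedding:
    """Rank-n protein and peptide factor vectors from one factorization.

    ``imputed`` records, for each allele embedded by imputation, the allele
    whose vector it borrows.
    """

    dimension: int
    vectors: Dict[HLAAllele, np.ndarray]
    peptide_factors: Dict[str, np.ndarray]
    training_meta: Dict[str, object]
    imputed: Dict[HLAAllele, HLAAllele] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v in list(self.vectors.values()) + list(self.peptide_factors.values()):
            if v.shape != (self.dimension,):
                raise EmbeddingError("embedding vectors must share one dimension")

    def save(self, prefix: str | Path) -> None:
        """Serialize as a JSON metadata file plus a delimited vector table."""
        prefix = Path(prefix)
        meta = {
            "dimension": self.dimension,
            "training_meta": self.training_meta,
            "imputed": {k.name: v.name for k, v in self.imputed.items()},
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        rows = [
            {"kind": "protein", "id": a.name, **{f"v{k}": x for k, x in enumerate(vec)}}
            for a, vec in sorted(self.vectors.items())
        ] + [
            {"kind": "peptide", "id": q, **{f"v{k}": x for k, x in enumerate(vec)}}
            for q, vec in sorted(self.peptide_factors.items())
        ]
        pd.DataFrame(rows).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)


def _solve_rows(
    factors: np.ndarray,
    values: np.ndarray,
    observed: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Ridge least-squares update of one factor block, row by row."""
    rank = factors.shape[1]
    out = np.empty((values.shape[0], rank))
    eye = np.eye(rank)
    for i in range(values.shape[0]):
        mask = observed[i]
        F = factors[mask]
        out[i] = np.linalg.solve(F.T @ F + lam * eye, F.T @ values[i, mask])
    return out


def _objective(P: np.ndarray, Q: np.ndarray, aff: AffinityMatrix, lam: float) -> float:
    resid = aff.values - P @ Q.T
    sq = float((resid[aff.observed] ** 2).sum())
    return sq + lam * (float((P ** 2).sum()) + float((Q ** 2).sum()))


def factorize(
    aff: AffinityMatrix,
    rank: int = 10,
    regularization: float = 0.01,
    max_iter: int = 200,
    tol: float = 1e-9,
    seed: int = 0,
) -> ProteinEmbedding:
    """Factorize an affinity matrix by alternating least squares.

    Peptide factors are initialized from a seeded Gaussian; protein and
    peptide blocks are then updated alternately by ridge least squares on
    the observed entries.  Convergence is declared when the relative
    objective decrease falls below ``tol``; non-convergence within
    ``max_iter`` is recorded in ``training_meta`` (result still returned).

    A matrix factorization is only determined up to an invertible change of
    basis of the latent space, which would make inner products between
    protein vectors arbitrary.  The returned factors are therefore
    gauge-fixed through the SVD of the fitted low-rank product
    (P = U sqrt(S), Q = V sqrt(S)), so protein-protein inner products are a
    property of the fitted matrix alone.
    """
    n_prot, n_pep = len(aff.proteins), len(aff.peptides)
    if rank > min(n_prot, n_pep):
        raise EmbeddingError(
            f"rank {rank} exceeds min(#proteins={n_prot}, #peptides={n_pep})"
        )
    if regularization < 0:
        raise EmbeddingError("regularization must be >= 0")
    rng = np.random.default_rng(seed)
    Q = rng.standard_normal((n_pep, rank)) / math.sqrt(rank)
    P = np.zeros((n_prot, rank))
    lam = float(regularization)
    # lam=0 with a deficient design would be singular; nudge only the solve
    solve_lam = lam if lam > 0 else 1e-12
    prev = math.inf
    objective = math.nan
    converged = False
    iterations = 0
    trace = []
    for iterations in range(1, max_iter + 1):
        P = _solve_rows(Q, aff.values, aff.observed, solve_lam)
        Q = _solve_rows(P, aff.values.T, aff.observed.T, solve_lam)
        objective = _objective(P, Q, aff, lam)
        trace.append(objective)
        if math.isfinite(prev) and prev - objective <= tol * max(abs(prev), 1e-300):
            converged = True
            break
        prev = objective
    # gauge fixing: symmetric SVD factors of the fitted product
    U, S, Vt = np.linalg.svd(P @ Q.T, full_matrices=False)
    root_s = np.sqrt(S[:rank])
    P = U[:, :rank] * root_s
    Q = Vt[:rank].T * root_s
    meta = {
        "rank": rank,
        "regularization": lam,
        "iterations": iterations,
        "max_iter": max_iter,
        "seed": seed,
        "converged": converged,
        "objective": objective,
        "objective_trace": trace,
    }
    return ProteinEmbedding(
        dimension=rank,
        vectors={p: P[i].copy() for i, p in enumerate(aff.proteins)},
        peptide_factors={q: Q[j].copy() for j, q in enumerate(aff.peptides)},
        training_meta=meta,
    )


def f3_similarity(emb: ProteinEmbedding, x: HLAAllele, y: HLAAllele) -> float:
    """Cosine-normalized inner product of two protein vectors."""
    try:
        vx, vy = emb.vectors[x], emb.vectors[y]
    except KeyError as exc:
        raise ResolutionError(f"allele {exc.args[0]} is not embedded") from exc
    nx, ny = float(np.linalg.norm(vx)), float(np.linalg.norm(vy))
    if nx == 0 or ny == 0:
        raise EmbeddingError(f"zero-norm embedding vector for {x if nx == 0 else y}")
    return float(vx @ vy) / (nx * ny)


def raw_inner_product(emb: ProteinEmbedding, x: HLAAllele, y: HLAAllele) -> float:
    """Unnormalized inner product of two protein vectors."""
    try:
        return float(emb.vectors[x] @ emb.vectors[y])
    except KeyError as exc:
        raise ResolutionError(f"allele {exc.args[0]} is not embedded") from exc


def impute_missing_protein(
    target: HLAAllele,
    emb: ProteinEmbedding,
    sequence_store: Mapping[HLAAllele, ProteinRecord],
    matrix: SubstitutionMatrix | None = None,
) -> HLAAllele:
    """Give a protein without affinity data the vector of its nearest neighbour.

    The substitute is the embedded same-locus protein with the highest
    normalized BLOSUM50 sequence similarity to the target (ties broken by
    lexicographically smallest allele name).  Imputing an already-embedded
    protein returns the protein itself and changes nothing.
    """
    if target in emb.vectors and target not in emb.imputed:
        return target
    if target in emb.imputed:
        return emb.imputed[target]
    matrix = matrix or load_bundled_matrix("blosum50")
    if target not in sequence_store:
        raise ResolutionError(f"no sequence record for {target}; cannot impute")
    candidates = [
        a for a in emb.vectors
        if a.locus == target.locus and a not in emb.imputed
    ]
    if not candidates:
        raise EmbeddingError(f"no embedded protein at locus {target.locus}")
    target_seq = sequence_store[target].sequence
    best: Tuple[float, HLAAllele] | None = None
    for cand in sorted(candidates):
        if cand not in sequence_store:
            continue
        sim = normalized_similarity(target_seq, sequence_store[cand].sequence, matrix)
        if best is None or sim > best[0]:
            best = (sim, cand)
    if best is None:
        raise ResolutionError(
            f"no embedded protein at locus {target.locus} has a sequence record"
        )
    substitute = best[1]
    emb.vectors[target] = emb.vectors[substitute]
    emb.imputed[target] = substitute
    return substitute


def make_f3(locus: str, emb: ProteinEmbedding) -> SimilarityFunction:
    """Wrap an embedding as the f3 similarity function for one locus."""

    def fn(x: HLAAllele, y: HLAAllele) -> float:
        for a in (x, y):
            if a.locus != locus:
                raise SimilarityError(f"allele {a} is not at locus {locus}")
        return f3_similarity(emb, x, y)

    return SimilarityFunction(kind="f3", locus=locus, _fn=fn)


def embed_cohort_locus(
    cohort_alleles: Sequence[HLAAllele],
    aff: AffinityMatrix,
    sequence_store: Mapping[HLAAllele, ProteinRecord],
    rank: int = 10,
    regularization: float = 0.01,
    max_iter: int = 200,
    tol: float = 1e-9,
    seed: int = 0,
) -> ProteinEmbedding:
    """Factorize one locus's affinity data and impute any cohort allele lacking it."""
    emb = factorize(aff, rank=rank, regularization=regularization,
                    max_iter=max_iter, tol=tol, seed=seed)
    for allele in sorted(set(cohort_alleles)):
        if allele not in emb.vectors:
            impute_missing_protein(allele, emb, sequence_store)
    return emb
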