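"""Couple-level allele-sharing features.

For a couple with maternal alleles (L1, L2) and paternal alleles (L3, L4)
at locus L, the feature for similarity function f is the mean of the four
maternal × paternal pairwise similarities:

    F(L) = (f(L1,L3) + f(L1,L4) + f(L2,L3) + f(L2,L4)) / 4

With three loci (A, B, C) and three functions (f1, f2, f3) each couple
yields 9 features, in the fixed locus-major column order
(A,f1) (A,f2) (A,f3) (B,f1) ... (C,f3).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .hla_model import (
    LABEL_RM,
    LOCI,
    Cohort,
    CoupleGenotype,
    HLAAllele,
    HLAModelError,
    ResolutionError,
)
from .similarity import SimilarityFunction

#: Fixed column order of the full feature matrix.
FEATURE_COLUMNS: Tuple[Tuple[str, str], ...] = tuple(
    (locus, kind) for locus in LOCI for kind in ("f1", "f2", "f3")
)

FunctionTable = Mapping[Tuple[str, str], SimilarityFunction]


def couple_feature(couple: CoupleGenotype, locus: str, f: SimilarityFunction) -> float:
    """Mean similarity of the four maternal × paternal allele pairs at one locus."""
    m1, m2 = couple.maternal[locus]
    p1, p2 = couple.paternal[locus]
    try:
        return (f(m1, p1) + f(m1, p2) + f(m2, p1) + f(m2, p2)) / 4.0
    except (ResolutionError, HLAModelError) as exc:
        raise ResolutionError(
            f"couple {couple.couple_id}, locus {locus}: {exc}"
        ) from exc


@dataclass
class FeatureMatrix:
    """Couples × features value matrix with aligned couple ids and labels."""

    couple_ids: List[str]
    columns: Tuple[Tuple[str, str], ...]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        n = len(self.couple_ids)
        if self.values.shape != (n, len(self.columns)):
            raise HLAModelError("feature matrix shape mismatch")
        if len(self.labels) != n:
            raise HLAModelError("label vector length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise HLAModelError("feature matrix contains non-finite values")

    @property
    def y(self) -> np.ndarray:
        """Binary label vector: 1 for the RM (positive) class, 0 otherwise."""
        return (self.labels == LABEL_RM).astype(int)

    def column_names(self) -> List[str]:
        return [f"{locus}_{kind}" for locus, kind in self.columns]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.column_names())
        df.insert(0, "couple_id", self.couple_ids)
        df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def select(self, column_idx: Sequence[int]) -> "FeatureMatrix":
        """A sub-matrix restricted to the given columns (order preserved)."""
        idx = list(column_idx)
        return FeatureMatrix(
            couple_ids=list(self.couple_ids),
            columns=tuple(self.columns[i] for i in idx),
            values=self.values[:, idx],
            labels=self.labels,
        )


def build_feature_matrix(cohort: Cohort, functions: FunctionTable) -> FeatureMatrix:
    """Build the full couples × 9 feature matrix in the fixed column order.

    ``functions`` maps (locus, kind) to a similarity function and must cover
    all 9 combinations.  Rows follow cohort order.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in functions]
    if missing:
        raise HLAModelError(f"missing similarity functions for columns: {missing}")
    values = np.empty((len(cohort.couples), len(FEATURE_COLUMNS)))
    for i, couple in enumerate(cohort.couples):
        for j, (locus, kind) in enumerate(FEATURE_COLUMNS):
            values[i, j] = couple_feature(couple, locus, functions[(locus, kind)])
    return FeatureMatrix(
        couple_ids=[c.couple_id for c in cohort.couples],
        columns=FEATURE_COLUMNS,
        values=values,
        labels=cohort.labels,
    )


BASELINE_COLUMNS = ("maternal_c2_count", "paternal_c2_count", "maternal_kir_aa")


def build_baseline_features(
    cohort: Cohort,
    c_group_table: Mapping[HLAAllele, str],
    kir_aa_flags: Mapping[str, int],
) -> pd.DataFrame:
    """Binary/count baseline features: C2 allele counts and KIR-AA homozygosity.

    ``c_group_table`` maps each HLA-C allele to "C1" or "C2";
    ``kir_aa_flags`` maps couple_id to the mother's KIR-AA homozygosity flag.
    """
    unmapped = sorted(
        {a.name for c in cohort.couples for a in (*c.maternal["C"], *c.paternal["C"])
         if a not in c_group_table}
    )
    if unmapped:
        raise HLAModelError(f"HLA-C alleles without C1/C2 assignment: {unmapped}")
    bad = {a.name: g for a, g in c_group_table.items() if g not in ("C1", "C2")}
    if bad:
        raise HLAModelError(f"invalid C-group values: {bad}")
    rows = []
    for c in cohort.couples:
        if c.couple_id not in kir_aa_flags:
            raise HLAModelError(f"no KIR-AA flag for couple {c.couple_id}")
        flag = int(kir_aa_flags[c.couple_id])
        if flag not in (0, 1):
            raise HLAModelError(f"KIR-AA flag for couple {c.couple_id} must be 0/1")
        rows.append(
            {
                "couple_id": c.couple_id,
                "maternal_c2_count": sum(c_group_table[a] == "C2" for a in c.maternal["C"]),
                "paternal_c2_count": sum(c_group_table[a] == "C2" for a in c.paternal["C"]),
                "maternal_kir_aa": flag,
            }
        )
    return pd.DataFrame(rows).set_index("couple_id")


def baseline_feature_matrix(
    cohort: Cohort,
    c_group_table: Mapping[HLAAllele, str],
    kir_aa_flags: Mapping[str, int],
) -> FeatureMatrix:
    """The baseline features wrapped as a FeatureMatrix for the classifier."""
    df = build_baseline_features(cohort, c_group_table, kir_aa_flags)
    return FeatureMatrix(
        couple_ids=[c.couple_id for c in cohort.couples],
        columns=tuple(("baseline", name) for name in BASELINE_COLUMNS),
        values=df.loc[[c.couple_id for c in cohort.couples], list(BASELINE_COLUMNS)].to_numpy(dtype=float),
        labels=cohort.labels,
    )
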