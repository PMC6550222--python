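"""Data model and readers for HLA class I genotype data.

Couples are typed at the three classical class I loci (HLA-A, -B, -C), two
alleles per parent per locus.  Alleles are identified by two-field
(protein-level) WHO nomenclature names such as ``A*01:01``; deeper field
designations (synonymous / non-coding variation) are truncated, because all
downstream similarity functions operate on the protein sequence or on
protein-level binding-affinity data, which two fields determine.

Protein sequences are expected pre-aligned per locus (the standard
distribution form of locus reference alignments); the loader validates equal
lengths rather than aligning.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Class I loci handled by the pipeline, in canonical order.
LOCI: Tuple[str, ...] = ("A", "B", "C")

#: The 20 standard amino-acid one-letter codes.
STANDARD_RESIDUES: Tuple[str, ...] = tuple("ARNDCQEGHILKMFPSTWYV")

#: Characters allowed in an aligned protein sequence.
GAP = "-"
ALLOWED_SEQUENCE_CHARS = frozenset(STANDARD_RESIDUES) | {GAP}

#: Recognised couple labels.
LABEL_RM = "RM"
LABEL_CONTROL = "control"
LABEL_UNKNOWN = "unknown"
LABELS = (LABEL_RM, LABEL_CONTROL, LABEL_UNKNOWN)


class HLAModelError(ValueError):
    """Base error for malformed genotype / sequence / matrix inputs."""


class AlleleParseError(HLAModelError):
    """Raised for WHO-nomenclature strings that cannot be parsed."""


class ResolutionError(HLAModelError):
    """Raised when an allele cannot be resolved to a required record."""


_ALLELE_RE = re.compile(r"^([ABC])\*(\d+):(\d+)(?::\d+)*[A-Z]?$")


@dataclass(frozen=True, order=True)
class HLAAllele:
    """A two-field HLA class I allele name, e.g. ``A*01:01``."""

    locus: str
    name: str

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise AlleleParseError(f"unknown locus {self.locus!r} in {self.name!r}")
        if not self.name.startswith(f"{self.locus}*"):
            raise AlleleParseError(
                f"allele name {self.name!r} does not match locus {self.locus!r}"
            )

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


def parse_allele(text: str) -> HLAAllele:
    """Parse a WHO-nomenclature allele string into a normalized two-field allele.

    Higher-field designations (``A*01:01:01``) and trailing expression
    suffixes (``C*04:09N``) are truncated to the protein-level two-field
    name.  Whitespace is stripped and the locus letter upper-cased.

    Raises
    ------
    AlleleParseError
        If the string lacks a ``*`` separator, names an unknown locus, or has
        non-numeric fields.
    """
    if not isinstance(text, str) or not text.strip():
        raise AlleleParseError(f"empty allele string: {text!r}")
    cleaned = "".join(text.split())
    if "*" in cleaned:
        locus_part, _, rest = cleaned.partition("*")
        cleaned = locus_part.upper() + "*" + rest
    m = _ALLELE_RE.match(cleaned)
    if m is None:
        raise AlleleParseError(f"malformed HLA allele string: {text!r}")
    locus, f1, f2 = m.group(1), m.group(2), m.group(3)
    return HLAAllele(locus=locus, name=f"{locus}*{f1}:{f2}")


@dataclass(frozen=True)
class ProteinRecord:
    """An aligned protein sequence for one allele.

    The sequence alphabet is the 20 standard residues plus the gap
    character ``-``; all records at one locus must share one aligned length.
    """

    allele: HLAAllele
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise HLAModelError(f"empty sequence for {self.allele}")
        bad = set(self.sequence) - ALLOWED_SEQUENCE_CHARS
        if bad:
            raise HLAModelError(
                f"sequence for {self.allele} contains disallowed characters {sorted(bad)}"
            )


PairOfAlleles = Tuple[HLAAllele, HLAAllele]


@dataclass(frozen=True)
class CoupleGenotype:
    """One couple: two maternal and two paternal alleles at each class I locus.

    Homozygosity (identical alleles within a parent) is permitted.
    """

    couple_id: str
    maternal: Mapping[str, PairOfAlleles]
    paternal: Mapping[str, PairOfAlleles]
    label: str = LABEL_UNKNOWN

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise HLAModelError(
                f"couple {self.couple_id}: label {self.label!r} not one of {LABELS}"
            )
        for parent_name, parent in (("maternal", self.maternal), ("paternal", self.paternal)):
            for locus in LOCI:
                pair = parent.get(locus)
                if pair is None or len(pair) != 2:
                    raise HLAModelError(
                        f"couple {self.couple_id}: {parent_name} genotype needs "
                        f"exactly 2 alleles at locus {locus}"
                    )
                for allele in pair:
                    if allele.locus != locus:
                        raise HLAModelError(
                            f"couple {self.couple_id}: allele {allele} filed under locus {locus}"
                        )

    def alleles(self) -> List[HLAAllele]:
        """All 12 allele slots of the couple (with repetition)."""
        out: List[HLAAllele] = []
        for locus in LOCI:
            out.extend(self.maternal[locus])
            out.extend(self.paternal[locus])
        return out


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric amino-acid substitution score table.

    Stored densely over its residue alphabet; indexable with a residue pair:
    ``m["A", "W"]``.
    """

    name: str
    residues: Tuple[str, ...]
    values: np.ndarray  # square, symmetric, aligned with `residues`
    _index: Mapping[str, int] = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.residues), len(self.residues)):
            raise HLAModelError(f"matrix {self.name}: shape/alphabet mismatch")
        if not np.array_equal(values, values.T):
            raise HLAModelError(f"matrix {self.name}: not symmetric")
        missing = set(STANDARD_RESIDUES) - set(self.residues)
        if missing:
            raise HLAModelError(
                f"matrix {self.name}: missing standard residues {sorted(missing)}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "_index", {r: i for i, r in enumerate(self.residues)})

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])

    def encode(self, sequence: str) -> np.ndarray:
        """Map a sequence to integer codes into this matrix; gaps become -1."""
        idx = self._index
        return np.fromiter(
            (idx[c] if c != GAP else -1 for c in sequence), dtype=np.int64, count=len(sequence)
        )


def load_substitution_matrix(source: str | Path | io.TextIOBase, name: str | None = None) -> SubstitutionMatrix:
    """Read an NCBI-style square substitution matrix text file.

    Format: optional ``#`` comment lines, a header row of residues, then one
    labelled row per residue.  The matrix must be exactly symmetric and cover
    at least the 20 standard residues.
    """
    if isinstance(source, (str, Path)):
        path = Path(source)
        text = path.read_text()
        name = name or path.stem
    else:
        text = source.read()
        name = name or "matrix"
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise HLAModelError(f"matrix {name}: no data lines")
    header = lines[0].split()
    n = len(header)
    rows: Dict[str, List[float]] = {}
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != n + 1:
            raise HLAModelError(f"matrix {name}: malformed row {ln!r}")
        try:
            rows[parts[0]] = [float(x) for x in parts[1:]]
        except ValueError as exc:
            raise HLAModelError(f"matrix {name}: non-numeric entry in row {ln!r}") from exc
    if set(rows) != set(header):
        raise HLAModelError(f"matrix {name}: row labels do not match header")
    values = np.array([rows[r] for r in header], dtype=float)
    asym = np.abs(values - values.T).max()
    if asym > 0:
        raise HLAModelError(f"matrix {name}: asymmetric (max |s_ab - s_ba| = {asym})")
    return SubstitutionMatrix(name=name, residues=tuple(header), values=values)


def write_substitution_matrix(matrix: SubstitutionMatrix, path: str | Path) -> None:
    """Write a matrix back in the NCBI-style text format read by the loader."""
    lines = [f"# {matrix.name}", "   " + " ".join(f"{r:>12s}" for r in matrix.residues)]
    for i, r in enumerate(matrix.residues):
        lines.append(r + " " + " ".join(f"{v:12.10g}" for v in matrix.values[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_bundled_matrix(name: str) -> SubstitutionMatrix:
    """Load one of the matrices shipped with the package.

    ``"blosum50"`` is the standard NCBI BLOSUM50 table. ``"pmbec_synthetic"``
    is a synthetic covariance-style matrix built from physicochemical
    descriptor profiles; it plays the role of a peptide-binding-energy
    covariance matrix and carries no experimental binding data.
    """
    from importlib import resources

    ref = resources.files("hlamatch") / "matrices" / f"{name.lower()}.txt"
    if not ref.is_file():
        raise HLAModelError(f"no bundled matrix named {name!r}")
    with ref.open("r") as fh:
        return load_substitution_matrix(fh, name=name.upper())


@dataclass
class Cohort:
    """An ordered couple list plus the protein records their alleles resolve to."""

    couples: List[CoupleGenotype]
    sequences: Dict[HLAAllele, ProteinRecord]

    def __post_init__(self) -> None:
        if not self.couples:
            raise HLAModelError("no couples")
        ids = [c.couple_id for c in self.couples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise HLAModelError(f"duplicate couple_id(s): {sorted(dupes)}")
        missing = sorted(
            {str(a) for c in self.couples for a in c.alleles() if a not in self.sequences}
        )
        if missing:
            raise ResolutionError(f"alleles without sequence records: {missing}")
        # per-locus aligned length check
        lengths: Dict[str, int] = {}
        for rec in self.sequences.values():
            ln = lengths.setdefault(rec.allele.locus, len(rec.sequence))
            if len(rec.sequence) != ln:
                raise HLAModelError(
                    f"locus {rec.allele.locus}: sequences not pre-aligned "
                    f"({rec.allele} has length {len(rec.sequence)}, expected {ln})"
                )

    def __len__(self) -> int:
        return len(self.couples)

    @property
    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.couples], dtype=object)

    def alleles_at(self, locus: str) -> List[HLAAllele]:
        """Distinct alleles of the cohort at one locus, sorted by name."""
        return sorted({a for c in self.couples for a in c.alleles() if a.locus == locus})


def genotype_columns() -> List[str]:
    """Canonical genotype table columns after couple_id and label."""
    return [
        f"{parent}_{locus}_{i}"
        for parent in ("mother", "father")
        for locus in LOCI
        for i in (1, 2)
    ]


def read_genotype_table(path: str | Path) -> List[CoupleGenotype]:
    """Read a delimited genotype table (one couple per row).

    Expected columns: ``couple_id``, ``label``, then
    ``{mother,father}_{A,B,C}_{1,2}``. Unknown extra columns are ignored with
    a warning. Tab- and comma-separated files are both accepted.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = ["couple_id", "label"] + genotype_columns()
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise HLAModelError(f"genotype table missing columns: {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("genotype table: ignoring unknown columns %s", extra)
    if df.empty:
        raise HLAModelError("no couples in genotype table")
    couples = []
    for _, row in df.iterrows():
        maternal = {
            locus: (parse_allele(row[f"mother_{locus}_1"]), parse_allele(row[f"mother_{locus}_2"]))
            for locus in LOCI
        }
        paternal = {
            locus: (parse_allele(row[f"father_{locus}_1"]), parse_allele(row[f"father_{locus}_2"]))
            for locus in LOCI
        }
        couples.append(
            CoupleGenotype(
                couple_id=str(row["couple_id"]),
                maternal=maternal,
                paternal=paternal,
                label=str(row["label"]),
            )
        )
    return couples


def write_genotype_table(couples: Sequence[CoupleGenotype], path: str | Path) -> None:
    """Write couples in the canonical tab-separated genotype table format."""
    rows = []
    for c in couples:
        row = {"couple_id": c.couple_id, "label": c.label}
        for parent, geno in (("mother", c.maternal), ("father", c.paternal)):
            for locus in LOCI:
                row[f"{parent}_{locus}_1"] = geno[locus][0].name
                row[f"{parent}_{locus}_2"] = geno[locus][1].name
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sequences(path: str | Path) -> Dict[HLAAllele, ProteinRecord]:
    """Read aligned protein sequences from FASTA (record id = allele name)."""
    store: Dict[HLAAllele, ProteinRecord] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        allele = parse_allele(rec.id)
        store[allele] = ProteinRecord(allele=allele, sequence=str(rec.seq).upper())
    return store


def write_sequences(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as FASTA keyed by normalized allele name."""
    with open(path, "w") as fh:
        for rec in sorted(records, key=lambda r: r.allele):
            fh.write(f">{rec.allele.name}\n{rec.sequence}\n")


def load_cohort(genotype_table: str | Path, sequence_file: str | Path) -> Cohort:
    """Load a full cohort: genotype table plus FASTA of aligned proteins.

    Every allele referenced by any couple must resolve to a sequence record;
    otherwise a :class:`ResolutionError` listing the missing alleles is
    raised.
    """
    couples = read_genotype_table(genotype_table)
    sequences = read_sequences(sequence_file)
    return Cohort(couples=couples, sequences=sequences)
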