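"""Synthetic cohort generator for end-to-end pipeline testing.

Emulates the study conditions of a case-control couple cohort typed at the
three HLA class I loci: per-locus allele pools derived from a root sequence
by point substitutions, a planted low-rank protein × peptide binding-affinity
matrix with optional missingness, couple genotypes drawn uniformly, C1/C2
and KIR-AA annotations, and labels whose log-odds depend on the couple's
true similarity features through a logistic model with tunable effect size:

    P(RM | couple) = sigmoid(alpha + beta * sum_j z(F_j)),   j in effect set

alpha is solved by root finding so the expected class split matches the
configured RM:control ratio, and the exact class counts are then enforced
by weighted sampling without replacement (selection probability proportional
to the propensity odds).  beta = 0 gives a pure null cohort; large beta with
label_noise = 0 gives a near-separable one.

The generator makes no attempt at population-genetic realism: no linkage
disequilibrium, no realistic allele-frequency spectrum, and no genetic
correlation between partners.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .embedding import AffinityMatrix, ProteinEmbedding, embed_cohort_locus, make_f3
from .features import FEATURE_COLUMNS, FeatureMatrix, build_feature_matrix
from .hla_model import (
    LABEL_CONTROL,
    LABEL_RM,
    LABEL_UNKNOWN,
    LOCI,
    STANDARD_RESIDUES,
    Cohort,
    CoupleGenotype,
    HLAAllele,
    ProteinRecord,
    write_genotype_table,
    write_sequences,
)
from .similarity import SimilarityFunction, make_f1, make_f2


class SyntheticDataError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a 95-couple case-control cohort (49 RM / 46 control)
    with 15 alleles per locus, 120-residue aligned proteins at 8% divergence
    from the locus root, a rank-4 affinity structure over 60 peptides with
    ~2.7% of entries unobserved, and a null (beta = 0) label model.
    """

    n_rm: int = 49
    n_control: int = 46
    alleles_per_locus: int = 15
    sequence_length: int = 120
    mutation_rate: float = 0.08
    n_peptides: int = 60
    planted_rank: int = 4
    affinity_noise_sd: float = 0.05
    missing_affinity_fraction: float = 0.027
    n_unassayed_alleles: int = 0
    effect_size: float = 0.0
    effect_features: Optional[Tuple[int, ...]] = None
    label_noise: float = 0.0
    kir_aa_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rm + self.n_control < 4 or min(self.n_rm, self.n_control) < 2:
            raise SyntheticDataError("need at least 2 couples per class")
        if not 0.0 <= self.missing_affinity_fraction < 1.0:
            raise SyntheticDataError("missing_affinity_fraction must lie in [0, 1)")
        if self.alleles_per_locus < 2:
            raise SyntheticDataError("alleles_per_locus must be >= 2")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise SyntheticDataError("mutation_rate must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise SyntheticDataError("label_noise must lie in [0, 1]")
        if self.n_unassayed_alleles >= self.alleles_per_locus:
            raise SyntheticDataError("n_unassayed_alleles must leave assayed alleles")
        if self.planted_rank > min(self.alleles_per_locus - self.n_unassayed_alleles,
                                   self.n_peptides):
            raise SyntheticDataError("planted_rank exceeds assayed matrix dimensions")
        if self.effect_features is not None:
            bad = [j for j in self.effect_features
                   if not 0 <= j < len(FEATURE_COLUMNS)]
            if bad:
                raise SyntheticDataError(f"effect_features indices out of range: {bad}")

    @property
    def n_couples(self) -> int:
        return self.n_rm + self.n_control

    @property
    def effect_indices(self) -> Tuple[int, ...]:
        if self.effect_features is None:
            return tuple(range(len(FEATURE_COLUMNS)))
        return tuple(self.effect_features)


@dataclass
class SyntheticDataset:
    """A generated cohort plus every annotation and the generating truth."""

    config: SyntheticCohortConfig
    cohort: Cohort
    affinities: Dict[str, AffinityMatrix]
    embeddings: Dict[str, ProteinEmbedding]
    functions: Dict[Tuple[str, str], SimilarityFunction]
    true_features: FeatureMatrix
    c_group: Dict[HLAAllele, str]
    kir_aa: Dict[str, int]
    ground_truth: Dict[str, object]


def _allele_name(locus: str, k: int) -> str:
    # WHO-pattern-valid synthetic names in an unused high series
    return f"{locus}*{90 + k // 99}:{k % 99 + 1:02d}"


def generate_allele_pool(
    cfg: SyntheticCohortConfig, locus: str, seed_seq: np.random.SeedSequence
) -> Tuple[List[ProteinRecord], AffinityMatrix, Dict[str, np.ndarray]]:
    """One locus's allele pool with sequences and planted low-rank affinities.

    Each allele is the locus root sequence with i.i.d. substitutions at
    ``mutation_rate``.  The affinity matrix over the assayed alleles is the
    planted product P0 Q0^T plus Gaussian noise, with entries masked
    uniformly at ``missing_affinity_fraction``; the last
    ``n_unassayed_alleles`` alleles get no affinity row at all (downstream
    imputation targets).
    """
    rng = np.random.default_rng(seed_seq)
    residues = np.array(STANDARD_RESIDUES)
    root = rng.integers(0, len(residues), size=cfg.sequence_length)
    records: List[ProteinRecord] = []
    for k in range(cfg.alleles_per_locus):
        seq = root.copy()
        mutate = rng.random(cfg.sequence_length) < cfg.mutation_rate
        # substitute to a uniformly random *different* residue
        shift = rng.integers(1, len(residues), size=cfg.sequence_length)
        seq[mutate] = (seq[mutate] + shift[mutate]) % len(residues)
        allele = HLAAllele(locus=locus, name=_allele_name(locus, k))
        records.append(ProteinRecord(allele=allele, sequence="".join(residues[seq])))

    n_assayed = cfg.alleles_per_locus - cfg.n_unassayed_alleles
    P0 = rng.standard_normal((n_assayed, cfg.planted_rank))
    Q0 = rng.standard_normal((cfg.n_peptides, cfg.planted_rank)) / np.sqrt(cfg.planted_rank)
    values = P0 @ Q0.T + cfg.affinity_noise_sd * rng.standard_normal((n_assayed, cfg.n_peptides))
    observed = rng.random(values.shape) >= cfg.missing_affinity_fraction
    # keep every row identifiable
    for i in range(n_assayed):
        if observed[i].sum() < 5:
            observed[i, rng.permutation(cfg.n_peptides)[:5]] = True
    aff = AffinityMatrix(
        proteins=[r.allele for r in records[:n_assayed]],
        peptides=[f"pep{locus}{j:03d}" for j in range(cfg.n_peptides)],
        values=values,
        observed=observed,
    )
    truth = {"P0": P0, "Q0": Q0}
    return records, aff, truth


def _draw_couples(
    cfg: SyntheticCohortConfig,
    pools: Dict[str, List[ProteinRecord]],
    rng: np.random.Generator,
) -> List[CoupleGenotype]:
    couples = []
    for i in range(cfg.n_couples):
        maternal, paternal = {}, {}
        for locus in LOCI:
            alleles = [r.allele for r in pools[locus]]
            pick = rng.integers(0, len(alleles), size=4)
            maternal[locus] = (alleles[pick[0]], alleles[pick[1]])
            paternal[locus] = (alleles[pick[2]], alleles[pick[3]])
        couples.append(
            CoupleGenotype(
                couple_id=f"couple{i + 1:03d}",
                maternal=maternal,
                paternal=paternal,
                label=LABEL_UNKNOWN,
            )
        )
    return couples


def _assign_labels(
    cfg: SyntheticCohortConfig,
    true_values: np.ndarray,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, Dict[str, object]]:
    """Labels from the logistic model with exact class counts enforced."""
    z = true_values - true_values.mean(axis=0)
    sd = true_values.std(axis=0)
    z = np.where(sd > 0, z / np.where(sd > 0, sd, 1.0), 0.0)
    s = z[:, list(cfg.effect_indices)].sum(axis=1)
    beta = cfg.effect_size
    n, n_rm = cfg.n_couples, cfg.n_rm

    def expected_rm(alpha: float) -> float:
        return float(expit(alpha + beta * s).sum()) - n_rm

    lo, hi = -700.0, 700.0
    alpha = brentq(expected_rm, lo, hi, xtol=1e-10)
    if abs(expected_rm(alpha)) > 1.0:
        raise SyntheticDataError(
            "class balance unreachable at this effect size; reduce effect_size"
        )
    logits = alpha + beta * s
    propensity = expit(logits)
    # weighted sampling without replacement, weight = propensity odds
    # (Efraimidis-Spirakis keys, kept in log-odds space so extreme effect
    # sizes cannot saturate); exact n_rm couples become RM
    if cfg.label_noise > 0:
        noisy = (1.0 - cfg.label_noise) * propensity + cfg.label_noise * 0.5
        log_odds = np.log(noisy) - np.log1p(-noisy)
    else:
        log_odds = logits
    keys = np.log(-np.log(rng.random(n))) - log_odds
    rm_idx = np.argsort(keys, kind="stable")[:n_rm]
    labels = np.full(n, LABEL_CONTROL, dtype=object)
    labels[rm_idx] = LABEL_RM
    truth = {
        "alpha": float(alpha),
        "beta": float(beta),
        "effect_indices": list(cfg.effect_indices),
        "linear_score": s.tolist(),
        "propensity": propensity.tolist(),
    }
    return labels, truth


def generate_cohort(cfg: SyntheticCohortConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset under one configuration.

    Deterministic given ``cfg`` (one seed fans out to per-stage streams).
    The couple's true features are computed with the pipeline's own
    similarity functions (f1/f2 on the generated sequences, f3 from
    factorizing the generated affinities at the planted rank).
    """
    root = np.random.SeedSequence(cfg.seed)
    seq_pool, seq_geno, seq_label, seq_annot, seq_embed = root.spawn(5)

    pools: Dict[str, List[ProteinRecord]] = {}
    affinities: Dict[str, AffinityMatrix] = {}
    planted: Dict[str, Dict[str, np.ndarray]] = {}
    for locus, child in zip(LOCI, seq_pool.spawn(len(LOCI))):
        pools[locus], affinities[locus], planted[locus] = generate_allele_pool(
            cfg, locus, child
        )
    sequences = {r.allele: r for recs in pools.values() for r in recs}

    rng_geno = np.random.default_rng(seq_geno)
    couples = _draw_couples(cfg, pools, rng_geno)
    cohort = Cohort(couples=couples, sequences=sequences)

    embed_seed = int(seq_embed.generate_state(1)[0] % (2**31))
    embeddings = {
        locus: embed_cohort_locus(
            cohort.alleles_at(locus),
            affinities[locus],
            sequences,
            rank=cfg.planted_rank,
            regularization=1e-3,
            seed=embed_seed,
        )
        for locus in LOCI
    }
    functions: Dict[Tuple[str, str], SimilarityFunction] = {}
    for locus in LOCI:
        functions[(locus, "f1")] = make_f1(locus, sequences)
        functions[(locus, "f2")] = make_f2(locus, sequences)
        functions[(locus, "f3")] = make_f3(locus, embeddings[locus])

    unlabeled = build_feature_matrix(cohort, functions)
    rng_label = np.random.default_rng(seq_label)
    labels, label_truth = _assign_labels(cfg, unlabeled.values, rng_label)

    labelled_couples = [replace(c, label=labels[i]) for i, c in enumerate(couples)]
    cohort = Cohort(couples=labelled_couples, sequences=sequences)
    true_features = FeatureMatrix(
        couple_ids=unlabeled.couple_ids,
        columns=unlabeled.columns,
        values=unlabeled.values,
        labels=labels,
    )

    rng_annot = np.random.default_rng(seq_annot)
    c_group = {
        r.allele: ("C2" if rng_annot.random() < 0.5 else "C1") for r in pools["C"]
    }
    kir_aa = {
        c.couple_id: int(rng_annot.random() < cfg.kir_aa_rate) for c in labelled_couples
    }

    ground_truth: Dict[str, object] = {
        **label_truth,
        "feature_columns": true_features.column_names(),
        "true_features": true_features.values.tolist(),
        "planted_rank": cfg.planted_rank,
        "seed": cfg.seed,
    }
    return SyntheticDataset(
        config=cfg,
        cohort=cohort,
        affinities=affinities,
        embeddings=embeddings,
        functions=functions,
        true_features=true_features,
        c_group=c_group,
        kir_aa=kir_aa,
        ground_truth=ground_truth,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> Dict[str, Path]:
    """Write the dataset in the exact input formats the pipeline readers expect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": outdir / "genotypes.tsv",
        "sequences": outdir / "sequences.fasta",
        "affinity": outdir / "affinity.tsv",
        "c_groups": outdir / "c_groups.tsv",
        "kir_aa": outdir / "kir_aa.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_genotype_table(ds.cohort.couples, paths["genotypes"])
    write_sequences(ds.cohort.sequences.values(), paths["sequences"])
    frames = []
    for locus in LOCI:
        aff = ds.affinities[locus]
        rows = [
            {"protein_allele": p.name, "peptide_id": q, "value": aff.values[i, j]}
            for i, p in enumerate(aff.proteins)
            for j, q in enumerate(aff.peptides)
            if aff.observed[i, j]
        ]
        frames.append(pd.DataFrame(rows))
    pd.concat(frames, ignore_index=True).to_csv(paths["affinity"], sep="\t", index=False)
    pd.DataFrame(
        [{"allele": a.name, "group": g} for a, g in sorted(ds.c_group.items())]
    ).to_csv(paths["c_groups"], sep="\t", index=False)
    pd.DataFrame(
        [{"couple_id": cid, "kir_aa": flag} for cid, flag in ds.kir_aa.items()]
    ).to_csv(paths["kir_aa"], sep="\t", index=False)
    paths["ground_truth"].write_text(json.dumps(ds.ground_truth, indent=2))
    return paths
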