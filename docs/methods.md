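# Methods

## Problem and model

Couples in which maternal and paternal HLA class I alleles are unusually
similar have repeatedly been associated with adverse pregnancy outcomes,
but the association is usually assessed with binary shared/not-shared
codings that discard most of the information carried by these highly
polymorphic loci. `hlamatch` implements a continuous alternative: each
couple is described by nine real-valued allele-sharing features, and a
linear-margin classifier evaluated under leave-one-out cross-validation
(LOOCV) turns those features into a per-couple risk score for recurrent
miscarriage (RM).

For a locus L ∈ {A, B, C} with maternal alleles (L1, L2) and paternal
alleles (L3, L4), and a protein-pair similarity f, the couple feature is

    F(L) = ( f(L1,L3) + f(L1,L4) + f(L2,L3) + f(L2,L4) ) / 4 ,

the mean similarity of the four maternal × paternal pairs.  Three
similarity functions are used per locus:

* **f1** — substitution-matrix sequence similarity under BLOSUM50;
* **f2** — the same construction under a covariance-style amino-acid
  matrix (see "Bundled matrices" below);
* **f3** — cosine similarity of binding-affinity embedding vectors.

Three loci × three functions give the fixed nine-column feature matrix
(A,f1) (A,f2) (A,f3) (B,f1) … (C,f3).

## Sequence similarity and its normalization

Sequences arrive pre-aligned per locus (the standard distribution form of
HLA protein reference alignments); the loaders validate equal lengths and
never align.  The raw score of two aligned sequences is the sum of
substitution-matrix entries over the positions where neither sequence has
a gap.  Raw scores are made commensurable across loci, matrices and
functions by cosine normalization

    s(x, y) = raw(x, y) / sqrt( raw(x, x) · raw(y, y) ) ,

with all three raw scores evaluated on the shared non-gap support of the
pair.  By Cauchy–Schwarz this bounds s in [−1, 1] and makes
self-similarity exactly 1.  The normalization requires positive
self-scores, which holds for any substitution matrix with positive
diagonal.

## The binding-affinity embedding (f3)

A protein × peptide affinity table (partially observed) is factorized per
locus by regularized alternating least squares (ALS) on the observed
entries:

    min_{P,Q}  Σ_observed (a_ij − p_i·q_j)² + λ(‖P‖² + ‖Q‖²)

ALS handles missing entries natively and is deterministic given the seed
of the Gaussian initialization of Q.  Because any factorization is only
determined up to an invertible change of latent basis — which would make
inner products between protein vectors meaningless — the returned factors
are gauge-fixed through the SVD of the fitted product (P = U√S, Q = V√S),
so protein–protein inner products are a property of the fitted matrix
alone.  f3 is the cosine of two protein vectors, giving self-similarity 1
like f1/f2.  The raw (unnormalized) inner product is available separately.

Defaults: embedding dimension 10, λ = 0.01, tolerance 1e−9 on the relative
objective decrease, at most 200 sweeps; the objective trace is recorded
and is non-increasing by construction.  Affinity values given as IC50
concentrations (nM) can be mapped to [0, 1] with the conventional
1 − log(IC50)/log(50000) transform; pre-transformed tables pass through
unchanged.

Proteins present in a cohort but absent from the affinity table borrow
the vector of the same-locus embedded protein with the highest f1
similarity (ties broken by lexicographically smallest allele name); every
imputation is recorded in the embedding and surfaced in the run log.

## Classification and cross-validation

The classifier is a linear-kernel SVM with margin constant C = 1 — the
only hyperparameter, deliberately left at its default; no model selection
is performed.  Under LOOCV each couple is scored by a model that never saw
it: feature standardization (z-scores), the SVM fit, and the score
calibration are all fitted on the other N−1 couples only.  A zero-variance
feature inside a training fold keeps scale 1 with a warning.

The decision value is mapped to a [0, 1] score by one of two calibrations:

* **rank** (default) — the empirical CDF of the training fold's decision
  values (ties get half weight).  This score is free of the training
  fold's class prior, which matters when scores are pooled across LOOCV
  folds: per-fold sigmoid calibration encodes the fold's class balance
  into each held-out score and biases the pooled null AUC measurably below
  0.5, a known pathology of pooled cross-validated scores.
* **platt** — a sigmoid (logistic regression) on the training decision
  values, returning a genuine class probability for threshold-based use,
  at the cost of the small pooling bias above.

RM is the positive class throughout.  The ROC curve sweeps all distinct
score thresholds with tied scores grouped; the trapezoidal AUC therefore
equals the Mann–Whitney pair statistic (#concordant + ½·#tied)/(pos·neg)
exactly.  Accuracy and sensitivity/specificity use a 0.5 threshold by
default, with ties classified positive.  The feature-addition curve ranks
features by single-feature LOOCV AUC (ties by column order) and re-runs
the full LOOCV on each top-k prefix.  Donor ranking forms a virtual couple
per candidate, scores it with a model trained on the full labelled cohort,
and sorts ascending by predicted RM probability (stable, ties by candidate
id).

## Significance

Two complementary arguments:

* **Label permutation.**  The label vector is uniformly shuffled and the
  entire LOOCV pipeline re-run per permutation (2000 by default); the
  p-value is the plain fraction of permuted statistics ≥ the observed one,
  with an exact zero reported as the bound "< 1/n_perm".  A `fast=True`
  mode switches to rank calibration, which cannot change the AUC statistic
  of any single run's scores and skips the per-fold sigmoid fit; it is off
  by default.
* **Binomial tail.**  The probability that a coin-flip classifier gets
  strictly more than a fraction q of n cases right,
  P(X ≥ ⌊qn⌋+1), X ~ Bin(n, ½), computed by exact integer summation.  For
  n = 95 and q = 0.67 this is ≈ 4.6 × 10⁻⁴.

## Synthetic cohorts

No genotype cohort of this kind is publicly distributable, so the package
ships a generator that emulates the study conditions end to end and serves
as the test bed for every stage:

* 95 couples (49 RM / 46 control) by default;
* 15 alleles per locus, derived from a random locus root sequence of 120
  residues by i.i.d. substitutions at rate 0.08 (≈ the divergence scale of
  class I protein variants);
* a planted rank-4 affinity structure over 60 peptides per locus with
  Gaussian noise (sd 0.05), entries masked uniformly at 2.7%, plus an
  optional count of entirely unassayed alleles to exercise imputation;
* C1/C2 assignments by fair coin per HLA-C allele and maternal KIR-AA
  flags at rate 0.3 — annotation plumbing for the baseline features, with
  no biological content;
* labels from a logistic model on the couple's true features:
  P(RM) = σ(α + β·Σ_j z(F_j)) over a configurable effect subset, with α
  solved by root finding so the expected split matches 49:46, and exact
  class counts then enforced by weighted sampling without replacement
  (Efraimidis–Spirakis keys computed in log-odds space, so extreme β
  cannot saturate).  β = 0 yields an exchangeable null; β = 10 with no
  label noise yields a near-separable cohort whose LOOCV AUC reaches 1
  within sampling error.

The generator is deterministic given its single seed (one seed sequence
fans out to per-stage streams) and writes the exact input formats the
loaders read.  It makes no attempt at population-genetic realism: no
linkage disequilibrium, no realistic allele-frequency spectrum, no genetic
correlation between partners, and independent loci.  Passing tests on
synthetic cohorts therefore demonstrate the correctness and calibration of
the machinery — not that real couples are classifiable.

## Bundled matrices

* `blosum50.txt` — the standard NCBI BLOSUM50 table (half-bit units).
* `pmbec_synthetic.txt` — a synthetic covariance-style matrix: the
  correlation of per-residue physicochemical descriptor profiles
  (Kyte–Doolittle hydropathy, residue volume, polarity, charge,
  isoelectric point).  It plays the role of a peptide-binding-energy
  covariance matrix in f2 and carries no experimental binding data; any
  symmetric matrix with positive diagonal can be supplied in its place.

## Numerical choices and degenerate inputs

* Substitution matrices must be exactly symmetric and cover the 20
  standard residues; asymmetric input is rejected rather than averaged.
* Sequence pairs with no shared non-gap position have undefined
  similarity and raise.
* ALS with λ = 0 uses a 1e−12 ridge in the per-row solves only, to keep
  deficient designs solvable without changing the objective.
* A LOOCV fold whose training labels are single-class raises (degenerate
  cohort); at least two couples per class are required.
* Problem sizes in the test suite (cohorts of 16–95 couples, 200
  permutations, 20 seeds per effect size, 100 calibration experiments)
  were chosen so the full statistical battery completes on a single CPU
  in well under half an hour while keeping Monte-Carlo error inside each
  test's stated band.

## Known limitations

* The two-field (protein-level) allele name is the canonical key; deeper
  field differences are collapsed.
* Class II loci are out of scope (no affinity data for f3; the framework
  itself is locus-agnostic).
* The f2 matrix shipped is a synthetic stand-in (above); results with it
  characterize the pipeline, not the published binding-energy covariance.
* Per-fold Platt calibration biases pooled LOOCV AUC slightly downward
  under the null; use the default rank calibration when the AUC is the
  quantity of interest.
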