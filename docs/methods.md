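# Methods

`phytodiv` implements the desk-side computations of a multi-assay genetic
characterization of plant accessions: dominant-marker band statistics,
accession clustering, DNA-barcode distances and bootstrap trees, relative
gene expression, and replicate-trait statistics. This note records the
models, the defaults and why, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Dominant-marker model

ISSR, SCoT and SDS-PAGE profiles are scored as binary band matrices: `A`
accessions × `B` bands, cell 1 when the band is present. A band is a
dominant biallelic locus — heterozygotes are indistinguishable from
dominant homozygotes — so the only observable per band is its presence
frequency `p = (accessions with band)/A`. Band classes follow from `p`
alone: monomorphic (`p = 1`), unique (carried by exactly one accession),
non-unique polymorphic (otherwise). Deriving classes from frequencies,
not from a fixed `A = 3`, keeps every statistic valid for any panel size.
All-zero band columns are rejected rather than dropped: a never-observed
band is a scoring artifact that should be surfaced, not hidden.

Per-primer panel, with `PB` polymorphic and `TB` total bands:

- **PIC** (default `band_2pq_mean`): mean over bands of
  `1 − p² − (1−p)² = 2p(1−p)`, bounded at 0.5 for dominant data. Published
  PIC columns are frequently not reproducible from band-class counts (the
  frequency definition used by survey papers is typically unstated), so
  `summarize` accepts per-primer overrides; an overridden primer is
  flagged `pic_method = external` and its MI uses the supplied PIC.
- **EMR** `= PB·(PB/TB)`: the polymorphic band count weighted by the
  polymorphic fraction. It satisfies `EMR ≤ TB` with equality exactly
  when every band is polymorphic (property-tested exhaustively for
  `TB ≤ 12`).
- **MI** `= PIC × EMR`.
- **RP** `= Σ Ib`. Default convention `doubled_frequency` (`Ib = 2p`,
  every monomorphic band contributes 2), the convention under which
  published three-accession RP columns recompute from class counts;
  the Prevost-style `Ib = 1 − 2|0.5 − p|` is available as `prevost`,
  and the CLI can report both.
- **P%** `= 100·PB/TB`; the multi-primer summary pools counts
  (`100·ΣPB/ΣTB`), never averages per-primer percentages.

Report tables round half-up to 2 decimals (the convention of printed
marker tables — e.g. an exact MI of 0.035 prints as 0.04); computation is
always full precision.

## Clustering

Binary-profile similarity defaults to Jaccard (joint absences carry no
signal for dominant bands); Dice and simple matching are options. A pair
of accessions with no bands at all is undefined under Jaccard/Dice and
raises instead of returning 0.

UPGMA is the textbook cluster-size-weighted average linkage, implemented
directly so that (a) merge heights are stored per node (half the merge
distance, hence ultrametric output whose cophenetic distances reproduce
an ultrametric input exactly), (b) ties break deterministically on the
lexicographically smallest cluster keys, and (c) internal nodes can carry
bootstrap supports. scipy's `average` linkage and `cophenet` serve as an
independent cross-check in the test suite, not as the implementation.

PCA is the SVD of the centered (optionally standardized) matrix;
eigenvalues are `s²/(n−1)`, explained percentages their shares, and the
sign of each component is fixed by making its largest-magnitude loading
positive. With three samples the centered matrix has rank ≤ 2, so
PC1+PC2 always explain 100% — the one property of a three-accession PCA
that is testable without the original attribute matrix. Heatmap
preparation scales each variable to `[−1, 1]` (or z-scores; constant
variables map to 0 with a warning) and orders rows/columns by UPGMA on
Euclidean distances of the scaled values.

## Barcodes

GC% counts G+C over unambiguous bases (optionally crediting the S code);
gaps never count. Pairwise identity uses a semi-global alignment
(match +1, mismatch −1, gap −2, free terminal gaps); identity is
matches over aligned columns excluding terminal-gap columns. Among
co-optimal alignments the highest-identity one (first 64 enumerated) is
reported — a deterministic tie-break that prefers an internal gap over a
terminal overhang explaining the same score.

Distances are uncorrected p-distances (proportion of differing
unambiguous sites) under pairwise or complete deletion; model-corrected
distances are out of scope. Bootstrap support resamples alignment
columns with replacement, rebuilds p-distance + UPGMA per replicate, and
scores each internal node by the percentage of replicates containing the
same leaf bipartition — bipartitions, not node identity, so support is
rotation-invariant. An alignment with no variable columns yields a
warning that supports carry no information.

## Relative expression

The Livak chain with efficiency fixed at 2 (no standard-curve
correction): per replicate `ΔCT = CT_target − CT_reference` (pairing by
replicate index), replicates averaged at the ΔCT level,
`ΔΔCT = ΔCT_sample − ΔCT_calibrator`, fold `= 2^−ΔΔCT`. The calibrator
sample has fold 1 by construction. Replicate spread is propagated as the
fold range over mean ΔCT ± SD(ΔCT) (`fold_lo`, `fold_hi`; `sd_fold` is
half that range). A constant well-to-well CT shift within a sample
cancels in ΔCT, so folds are invariant to it (property-tested).

## Trait statistics

One-way ANOVA is the classical between/within decomposition with p from
the F distribution; zero within-variance returns F = 0 (equal means) or
F = ∞. Duncan's multiple range test is computed from studentized-range
quantiles (`scipy.stats.studentized_range`, no table files) at Duncan's
protection level `alpha_k = 1 − (1−alpha)^(k−1)`: ordered means are
tested span-by-span with the step-down rule (a non-significant span is
not subdivided), maximal non-significant spans become shared letters,
letters assigned in descending-mean order. Unequal replicate counts use
the harmonic-mean n with a warning. Pearson matrices are offered at the
accession-mean level (flagged low-n with three accessions) or the
replicate level (pairing by accession and replicate index); a
zero-variance trait gives NaN with a warning, never a silent 0.

## Synthetic data

Generators are pure functions of (profile, seed); the packaged default
profile encodes a three-accession study with a close pair (C1, C2) and a
divergent third (C3):

- **Bands**: 21 primer compositions (10 ISSR totalling 70 bands, 11 SCoT
  totalling 138) plus a 7-band protein profile with 2 bands unique to C1.
  Unique-band owners honour per-accession quotas (ISSR 8/4/12,
  SCoT 23/7/29, protein 2/0/0); non-unique bands are shared by the close
  pair with probability 1/2 and by either far pair 1/4 each, reflecting
  the encoded genetic proximity. Class counts are realized exactly, so
  marker statistics are deterministic; only band placement varies with
  the seed.
- **Alignment**: i.i.d. site substitutions along an ultrametric
  three-taxon tree; defaults 600 bp, close-pair p-distance 0.01, far
  0.15 — a within-species vs congener-level contrast typical of
  ITS/18S barcodes. Realized distances match targets to first order
  (parallel/back substitutions bias them slightly low, well inside
  `3·sqrt(d(1−d)/L)`).
- **CT tables**: reference gene at 20 cycles, calibrator ΔCT 5 cycles,
  per-well N(0, 0.2²) noise, triplicates. Truth folds use C1 as
  calibrator; C3 folds (7.3, 14.6, 13.8) set the strong-upregulation
  regime of the emulated study, C2 intermediate values are plausible
  fill-ins. With σ = 0 the pipeline returns truth exactly; at σ = 0.2
  the fold estimate from triplicates has a log2 SD of ≈0.16, so a single
  estimate lies within 25% of truth with ≈95% probability — recovery is
  asserted as unbiasedness (geometric mean within 25%) plus ≥90/100
  seeded simulations individually inside the band.
- **Traits**: normal replicate noise (n = 3) around per-accession means;
  defaults use the emulated study's reported extremes with plausible
  values for unreported accessions, SD ≈ 5% of the mean.

What the generator does **not** emulate: gel mobility and fragment-size
structure, genotyping/scoring error (class counts are exact by
construction), indels and rate heterogeneity in sequences, qPCR
efficiency differences between genes, and non-normal or heteroscedastic
assay noise. Passing tests therefore demonstrate correctness of the
computations and recoverability under idealized noise, not robustness to
real-data artifacts.

## Problem sizes and determinism

Bootstrap demonstrations use 200 replicates on 300–600 bp toy
alignments, and recovery properties use 100 seeded simulations — sizes at
which every documented property is stable; production runs can raise
`--bootstrap` to the conventional 2000. All randomness flows through
`numpy.random.default_rng` seeds surfaced in every API and CLI entry
point, and the pipeline manifest records a SHA-256 per output so reruns
can be verified byte-for-byte.

## Known limitations

- Published PIC columns cannot be recomputed from band-class counts;
  they enter only as overrides.
- Dominant markers cannot separate heterozygotes; no Hardy–Weinberg
  back-estimation of allele frequencies is attempted.
- p-distances are uncorrected; trees are UPGMA only (molecular-clock
  assumption), no likelihood or parsimony methods.
- Pairwise identity is defined by one scoring scheme; values from other
  aligners (e.g. local alignment search tools) can differ.
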