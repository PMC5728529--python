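# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Evidence funnel

A gene is a gel-forming mucin candidate iff it passes three independent
layers:

* **Annotation.** Case-insensitive substring match of a keyword (default
  `"mucin"`) against the FASTA description line. An empty keyword matches
  everything.
* **Transcription.** Strictly greater than `fpkm_threshold` (default 1.0)
  in at least one tissue of the expression matrix. "Not transcribed" is
  the exact complement, FPKM ≤ 1 everywhere. Genes absent from the matrix
  are treated as not transcribed and logged, not errored: an annotation
  set and an expression panel routinely disagree on a few identifiers.
* **Domain structure.** The architecture contains VWD, C8, TIL
  consecutively in N→C order.

Stage counts are reported **within the annotated universe** (the
transcription and motif counts are of annotated genes), so the report reads
as a nested narrowing. The candidate set is the plain intersection and is
invariant under input order.

## PTS detection

PTS regions (Pro/Thr/Ser-rich O-glycosylation segments) have no Pfam model
and are detected compositionally. A window of `window` residues (default
100) qualifies when

* (count(S) + count(T)) / window **>** `st_min_frac` (default 0.40), and
* count(P) / window **≥** `pro_min_frac` (default 0.05).

The asymmetric strictness (> vs ≥) is deliberate and kept exactly as the
criterion is conventionally printed. Qualifying windows whose spans overlap
or abut are merged into maximal regions; each region records the maximum
per-window S+T and Pro fractions. Choices:

* "serine or threonine" is read as the pooled S+T fraction (the standard
  PTS usage); a `combined_st=False` mode requires a single residue class to
  clear the threshold alone, for sensitivity analysis.
* Stride defaults to 1; region maximality is defined (and tested, against
  exhaustive window enumeration) at stride 1. Larger strides are a strict
  subset.
* Sequences shorter than the window yield no regions — the statistic is
  defined at the full window only; there is no shrunken-window fallback.
* `X` counts toward window length but toward no composition class
  (conservative: unknowns never help a window qualify).

The scan uses cumulative residue counts and is linear in sequence length.

## Domain architectures

Domain hits are consumed from hmmscan per-domain tables (domtblout
dialect). Coordinates are the **envelope** columns (they bound the full
domain occurrence); all coordinates are 1-based inclusive throughout.
Unknown Pfam families map to `other`.

* **E-value filter**: keep hits with i-Evalue ≤ 1e-3 (default; the common
  Pfam practice, configurable).
* **Overlap resolution**: greedy in ascending i-Evalue (ties: higher
  score, then smaller start). A hit is kept iff its *coordinate overlap*
  min(end₁,end₂) − max(start₁,start₂) with every kept hit is ≤
  `overlap_tol` (default 10). Note this measure is the shared-residue
  count minus one for overlapping intervals; it is the measure the
  tolerance is defined against. The result is feasible (pairwise within
  tolerance) and deterministic, not necessarily maximum-cardinality.
* **Architecture**: kept hits and PTS regions interleaved by start. A PTS
  region overlapping a kept domain by more than the tolerance is truncated
  to its larger domain-free flank, or dropped if nothing remains.
* **Minimum mucin motif**: VWD-C8-TIL consecutive in N→C order. PTS
  elements are transparent to the match; any other domain blocks it (the
  cassette is read as contiguous). A fully-gapped mode is available via
  pre-filtering if ever needed; transparency of PTS alone is the default
  because PTS regions are compositional calls, not domains, and routinely
  interleave real cassettes.
* Rendering groups cassettes in parentheses, and optionally collapses
  repeats (`3X(VWD-C8-TIL-VWC)`); grouping is presentation only — equality
  is defined on the flat element sequence.
* **VWD extraction**: VWD elements are labelled D1…Dk by N-terminal rank;
  the labels drive the positional clustering question in the phylogeny
  (do D1 domains cluster with D1 domains across genes and species?).

## VWD phylogeny

Trees are neighbor joining on pairwise distances from a supplied protein
alignment (the alignment itself is produced externally, e.g. with mafft).

* **Distances**: p-distance (mismatches over pairwise non-gap columns;
  pairwise deletion maximises usable signal on short domain alignments) or
  its Poisson correction d = −ln(1 − p). A pair with no shared ungapped
  column, or p = 1 under Poisson, is an error naming the pair.
* **NJ**: standard Q-criterion agglomeration, ties broken by the lowest
  index pair, branch lengths un-clamped — additive matrices are therefore
  reproduced exactly by path lengths (tested to 1e-9), and the whole
  construction is deterministic.
* **Bootstrap**: columns resampled with replacement B times (default 100);
  the support of each internal bipartition of the full-data tree is the
  percentage of replicate trees containing it. Replicates with an
  undefined distance are skipped and logged; the effective replicate count
  is recorded on the tree. Pendant edges carry no support.
* **Rooting**: on the outgroup's pendant edge, split at its midpoint
  (the convention here: the fruit-fly Hemolectin VWD domain, the standard
  non-vertebrate mucin outgroup). Supports are re-attached to the same
  unrooted bipartitions after rerooting.

NJ on corrected distances replaces likelihood tree search by design: it is
self-contained, deterministic and testable against closed forms. It is a
different estimator than ML under WAG; on clean domain alignments the
family-level clustering (Muc2 vs Muc5; positional D-classes) is expected to
agree, but branch lengths are not comparable and no claim is made that the
two methods coincide in general.

## qPCR analysis

* **Duplicate QC** (default limit 0.5 cycles): the conventional rule
  retains a duplicate pair when |Ct₁ − Ct₂| < 0.5 and discards it
  otherwise. A `literal` mode implements the opposite (discard pairs that
  agree) because the rule is sometimes printed that way; the conventional
  reading is the default since the literal one would discard precisely the
  good wells. Singletons pass with a warning; more than two replicates per
  well is a data error.
* **Efficiency**: least squares of Ct on log10(relative concentration),
  E = 10^(−1/slope); ≥3 points required, non-negative slope is an error.
  Noiseless 1:2 series reproduce the generating E exactly.
* **Reference stability** (RefFinder-style aggregation): per candidate
  gene j over the samples in which *all* candidates were measured —
  geNorm M (mean over partners k of SD(Ct_j − Ct_k)); BestKeeper SD
  (raw SD of Ct_j); comparative-ΔCt (same pairwise-SD mean, kept as its
  own column as the methods are distinct in general); NormFinder-style
  (SD of the doubly-centred residual Ct_ji − rowmean − colmean +
  grandmean, i.e. spread not explained by sample and gene main effects —
  implemented without group strata). Genes are ranked per measure (average
  ranks on ties — with exactly two candidates the three pairwise measures
  tie by symmetry and BestKeeper discriminates) and aggregated by the
  geometric mean of ranks; lowest aggregate = most stable.
* **ΔCt**: Ct(target) − Ct(reference) per sample; samples missing the
  reference are dropped and logged; a reference missing entirely is an
  error.
* **Tissue profiles**: gene × tissue matrix of −mean(ΔCt) (inverted so
  higher = more transcript). Unmeasured combinations stay missing — an
  undetected transcript is absent, not at the reference level.
* **Group effects**: per gene × tissue, one-way fixed-effects model of ΔCt
  on group; each group is contrasted against the control with the pooled
  residual variance (algebraically identical to the OLS coefficient t-test
  under treatment coding; cross-checked against statsmodels in the test
  suite). log2FC = −(ΔCt̄_group − ΔCt̄_control); the control group is
  exactly 0 with no p-value. Significance at p < 0.05, two-sided, no
  multiple-testing correction (deliberately — the analysis this mirrors
  applies none, and the flag is a display aid, not an inference
  guarantee). Degenerate cases: identical groups give p = 1; a zero
  residual variance with a non-zero contrast gives the smallest positive
  float rather than 0 (p is reported in (0, 1]); singleton non-control
  groups get their effect but no p-value, logged. The baseline-mode
  analysis of a time-course (day 0 as control) is the same code path with
  the baseline group named as control.

## In-silico PCR

Exact matching only: the forward primer on the given strand, the reverse
primer as its reverse complement strictly downstream. Because PCR
amplifies a duplex, the flipped presentation (reverse primer literal,
reverse complement of the forward downstream) is searched as well, making
the predictor invariant to reverse-complementing the template. Products
are reported shortest first up to `max_products`; zero products is an
empty list. No mismatch tolerance, no thermodynamics — the assays this
verifies are exact designs, and degenerate matching is out of scope.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the funnel's three evidence layers with known ground
truth:

* **Proteomes.** True mucins are built from architecture templates (the
  Muc5-type 3×(VWD-C8-TIL-VWC)-PTS-(VWD-C8-TIL) and Muc2-type
  3×(VWD-C8-TIL)-PTS-(VWD-C8-TIL)); decoy modes each violate exactly one
  layer (annotated-not-transcribed, transcribed-without-motif,
  motif-not-annotated, shuffled cassette order), plus plain background
  proteins. Background residues come from a fixed S/T/P-poor frequency
  table (S+T ≈ 4%), so background can never qualify as PTS. Domain
  segments have fixed realistic lengths (VWD 170, C8 70, TIL 60, VWC 50
  aa) but random background composition — domain identity lives in the
  hit table, not in sequence content. Planted PTS segments (default 300
  aa, S+T 0.60, Pro 0.10) are drawn by rejection sampling until every
  100-residue window satisfies the detector criterion; for near-threshold
  targets a fixed-composition 100-mer is tiled instead (every window of a
  period-100 sequence has identical composition, so the guarantee is
  exact). Configurations whose PTS composition cannot clear the detector
  thresholds are rejected at validation.
* **Domain hits.** One hit per planted domain with i-Evalue in
  [1e-20, 1e-8]; optional false positives share the planted span with
  worse (but still sub-threshold) E-values, so overlap resolution must
  remove them.
* **Expression.** Nine-tissue panel (pyloric caeca, foregut, skin,
  pancreas, gill, spleen, liver, heart, brain). Transcribed genes get 1–3
  tissues at uniform(5, 300) FPKM; everything else is uniform(0, 1). The
  FPKM marginal distribution of real RNA-seq is not modelled (it is not
  specified by any constraint this package implements); only the
  above/below-threshold structure is meaningful, which is exactly what the
  funnel consumes.
* **qPCR.** Target Ct = baseline − effect + N(0, biological_sd) per fish;
  references drift with their own per-gene SD (mix stable ≈ 0.05 and
  unstable ≈ 0.4 candidates to exercise the stability ranking); every well
  is measured twice with N(0, duplicate_sd) replicate noise; five-point
  noiseless 1:2 dilution series per primer pair with slope
  −1/log10(E_true). Effects are in log2 units ≡ Ct cycles at doubling
  efficiency. Noise is Gaussian on the Ct scale, matching the linear
  modelling of ΔCt. Biological noise is drawn independently per fish and
  gene — nothing is shared within a fish — so reference normalisation
  removes no biological variance in the simulation; this is the
  conservative choice for testing the estimator.

Passing tests on these simulations therefore demonstrate correctness of
the algorithms against planted truth; they do not demonstrate robustness
to properties the generator does not model: annotation errors, partial
gene models, tandem-repeat assembly collapse inside PTS regions, Pfam
version drift in domain calls, FPKM normalisation artefacts, or qPCR
outliers and inhibition (non-Gaussian Ct error).

Default study sizes mirror the emulated designs: n = 15 fish per group for
the acute-stress layout, n = 12 for the time-course, technical duplicates,
two candidate reference genes, 100 bootstrap pseudoreplicates. Simulation
counts in the test suite (50 proteomes for funnel recovery, 200 sequences
for the PTS oracle, 100 additive matrices, 200 recovery and 1000 null qPCR
replicates) are sized to make the checks sharp while keeping the default
test run fast on a single CPU.

## Integration checks against public data (not run by the test suite)

With network access and the public inputs (the Atlantic salmon RefSeq
annotation GCF_000233375.1 and its protein sequences, a Pfam-A hmmscan of
those proteins, tissue FPKMs from SRA project PRJNA260929, and the seven
candidate protein accessions), the same pipeline supports two documented
checks: the funnel's nested counts on the real annotation
(144 → 52 → 25 → 7) and the total of 19 labelled VWD domains across the
seven candidates. Both are sensitive to annotation and Pfam versions, so
they are documented here as integration checks rather than encoded as unit
gates. The in-silico PCR subcommand reproduces the published amplicon
lengths when run on the corresponding RefSeq mRNAs.

## Known limitations

* The funnel's annotation layer is a keyword heuristic by design; it
  inherits whatever the upstream annotation calls a "mucin".
* NJ support values are column-bootstrap proportions on a distance method;
  they are not posterior probabilities and will differ from ML bootstrap.
* The NormFinder-style measure omits group strata (intra/inter-group
  variance decomposition) — with unstratified input the doubly-centred
  residual spread is the comparable quantity.
* With exactly two reference candidates, pairwise stability measures
  cannot separate the pair (a property of the measures, not the code);
  BestKeeper's raw SD carries the decision.
* In-silico PCR is exact-match; a primer with even one mismatch to the
  template reports no product.
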