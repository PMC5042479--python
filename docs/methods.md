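# Methods

This document describes the statistical and algorithmic methods implemented
in `isopipe`, in the order the analysis stages use them.

## 1. Gene model and theoretical isoform enumeration

A gene is described by a **region/sub-variant table**: an ordered list of
regions (5'→3' on the coding strand), each holding one or more mutually
exclusive *sub-variants*. A sub-variant is a chain of genomic intervals (an
empty chain encodes skipping), a kind (`start`, `internal`, `end`), an
optional `major` flag, and optional cross-region `requires`/`excludes`
constraints.

Enumeration takes the Cartesian product of one sub-variant per region, with
the last region varying fastest, drops combinations violating any constraint,
and numbers survivors from 1. Contradictory constraint pairs (X requires Y
while Y excludes X) are rejected up front. Exon chains are merged (touching
fragments joined, overlaps rejected) and splice junctions derived from the
gaps between consecutive exons.

The bundled toy gene has 8 regions and 21 sub-variants; the major flags give
24 major combinations (12/6/6 across the three alternative start sites), and
dropping all constraints gives the full 648-isoform combinatorial space.
Enumeration is a direct product over small lists and completes in
milliseconds.

## 2. Annotation flattening and feature counting

Known transcripts are flattened per gene into **disjoint exonic regions**:
every exon start/end from every transcript is a breakpoint, and each interval
between consecutive breakpoints covered by at least one exon becomes a region
(labels `E001…` 5'→3'). Deduplicated transcript junctions follow in the same
numbering (`J…`).

Aligned read pairs are read from SAM (primary alignments only; pair strand
follows the fr-secondstrand convention, read 1 carrying the transcript
strand). CIGAR `N` operations at least `min_intron` (default 20) long split
blocks and define junction gaps; shorter `N` and all `D` stay inside their
block.

**Novel-junction discovery**: every gap absent from the annotation and
supported by at least `min_support` (default 5) distinct read pairs across
samples is appended as a novel feature (`N…`, numbering continuing after the
known features). Donor/acceptor dinucleotides are reported so canonical GT–AG
junctions can be distinguished.

**Counting**: a pair increments an exonic region when any block overlaps it
by ≥ 1 base, and a junction when one of its gaps equals the junction exactly;
each pair counts at most once per feature. The gene total counts pairs
overlapping the gene span. Feature counts deliberately overlap (one pair can
support several features); they are never compared to the gene total by
summation, only through the usage contrast below.

**Size factors** are DESeq-style median-of-ratios over genes nonzero in all
samples, rescaled to geometric mean one, with a warned fallback to
total-count ratios when no gene qualifies.

## 3. Differential feature usage

For each feature the test contrasts two count rows per sample: the feature
count and the *gene rest* (gene total minus feature, floored at zero). The
model is an NB2 GLM with log link,

    log mu = beta0 + beta1·bin + beta2·condition + beta3·bin:condition + log sf

where `bin` indicates the feature row versus the rest row and `sf` is the
sample size factor (entering as an offset). The usage test is a 1-df
likelihood-ratio test of the interaction `beta3` — a shift in the feature's
share of its gene, insensitive to overall gene-expression changes. Fits use
iteratively reweighted least squares; non-converged fits return the p = 1
sentinel rather than an unreliable p-value.

### Dispersion estimation

Per-feature dispersions at n = 3+3 replicates are too noisy to use raw, so
the estimator follows the established shrinkage recipe:

1. **Raw per-feature dispersion**: maximise the Cox–Reid adjusted profile
   likelihood (APL) under the **full** design. Estimating under the reduced
   model would let genuine usage shifts inflate the dispersion, costing power
   exactly for the features of interest.
2. **Pooled common dispersion**: maximise the *summed* Cox–Reid APL across
   features (an evenly spaced subsample of at most 200 features bounds the
   cost). Unlike the median of noisy per-feature maxima — biased low at few
   residual degrees of freedom — the pooled maximiser is nearly unbiased, so
   it centres the prior.
3. **Prior width**: the robust (MAD-based) spread of the log raw estimates
   minus the expected sampling variance of a log-dispersion estimate,
   trigamma((n − p)/2), floored at 0.0625. The robust spread matters: raw
   estimates at 8 residual df have a heavy right tail that would otherwise
   widen the prior and undo the shrinkage.
4. **MAP estimate**: per-feature maximum of the APL plus a log-normal prior
   with that centre and width.

Features with mean normalised count below 6 are not tested.

### Multiplicity and summaries

Feature p-values are BH-adjusted. Gene-level p is the Šidák aggregate of the
gene's minimum feature p over its k tested features, 1 − (1 − p_min)^k,
BH-adjusted across genes; per-gene counts of significant features are broken
down by feature class (exonic region, known junction, novel junction), and a
threshold sweep reports genes hit at padj < 0.05/0.01/0.001.

### Calibration

The count simulator draws each feature count NB(gene_mean · usage · lib ·
shift, α) and forms the gene total as the sum of the gene's exonic feature
draws plus an independent NB background covering the remaining usage mass.
With one tested feature per gene the gene rest is then exactly an independent
NB draw with the feature's dispersion — precisely the model the test assumes —
so single-feature null genes are calibrated by construction and are the
configuration calibration studies should use. The acceptance suite verifies,
over 2,000 null features, that the type-I error at α = 0.05 and α = 0.01
stays inside the 99% binomial envelope, that a 3-fold usage shift at gene
mean 300 with 3+3 replicates is detected at p < 0.01 in ≥ 80% of features,
and that a 16-fold spike on a novel start-site junction is flagged at
padj < 0.05 in ≥ 90 of 100 replicates.

## 4. Long-read (ROI) classification

Theoretical **amplicons** pair each enumerated isoform with its primer pair:
name, genomic block structure and exact expected sequence. Amplicon sets are
`major` (the major combinations), `retention` (majors with the two-exon
b-terminal replaced by its intron-retained single block), and `minor`
(everything else in the unconstrained space). An index over these rejects
cross-isoform duplicate sequences (the theoretical set would be ambiguous).

Classification of each read of insert proceeds by strict precedence:

1. **Primer matching.** Each primer (and its reverse complement) is aligned
   semi-globally (edlib infix mode) against a terminal window of twice its
   length, in both read orientations, allowing ≤ 3 edits per primer; primers
   are not clipped. Both ends matching one pair consistently → full length
   (the read is normalised to sense orientation); one end → `one_end`;
   neither → `no_primer`.
2. **Alignment screening.** Reads without a primary alignment are
   `unaligned`; alignments on another contig or outside the gene span are
   `off_target_alignment`.
3. **Perfect match**: the normalised read sequence equals a major amplicon's
   sequence exactly (string equality) → `perfect_major`.
4. **Alignment match**, evaluated against majors, then retention, then minor
   amplicons. A read matches an amplicon when all four criteria hold: same
   set of covered exonic regions, same junction chain, nothing extra, and
   both alignment ends within 3 bp (inclusive) of the amplicon's primer
   endpoints. Intron retention is additionally recognised structurally: a
   single aligned block spanning a model intron end to end.
5. Otherwise `full_length_unmatched`.

Reads matching several isoforms equally are kept in their category but
excluded from per-isoform tallies (marked ambiguous). Reporting includes the
category summary, per-isoform perfect/alignment counts, and a tier table
(isoforms with ≥ 1000/500/50/1 perfect matches).

The test suite checks the classifier for *exact* agreement with a brute-force
oracle — naive dynamic-programming primer matching, direct string equality,
and a literal re-evaluation of the four alignment-match criteria — on a
simulated cohort over a compact gene whose amplicons stay under 500 nt, plus
explicit boundary cases at end offsets 3 (match) and 4 (no match).

## 5. Simulators

**Toy gene.** Deterministic from a seed: a single contig carrying 22 exons, a
Kozak-flanked 414-aa reference ORF with 8 designed protein domains, canonical
GT–AG introns, three alternative start sites, a frame-preserving cassette
exon (+10 aa), a frame-disrupting skippable exon, an alternative acceptor,
three alternative terminal exons, and nine primer pairs covering the
start/end combinations.

**Short reads.** Error-free paired spliced alignments drawn uniformly (or by
supplied weights) from chosen isoforms; fragment lengths uniform in 160–300,
read length 76, fr-secondstrand flags, truth table of per-pair blocks and
gaps.

**Counts.** As in §3; library factors default to exp(U(−0.3, 0.3)) normalised
to geometric mean one.

**ROIs.** Each read picks a major amplicon from a skewed abundance mixture
(weight ∝ 1/rank^1.3) or a retention/minor amplicon with configured
probabilities; non-full-length reads are truncated at one or both ends; a
configurable fraction of reads is error-free (consensus reads vary in pass
count, so many carry no residual errors), the rest receive per-base errors
(80% substitutions, 10% insertions, 10% deletions). FASTA reads, truth SAM
alignments and a truth table are emitted and cross-validated. Default mixture
proportions are calibration values documented on `ROISimConfig`; they are
defaults of the study design, not tuned quantities.
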