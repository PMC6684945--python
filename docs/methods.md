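# Methods

This note documents the models and procedures implemented in `follimir`, the
defaults they run with, and what the synthetic study does and does not
establish about real data.

## Read cleaning

Adapter removal takes the longest read suffix exactly matching a prefix of
the 3' adapter (minimum overlap 6 nt). Exact matching keeps the stage
deterministic; no quality information is used anywhere (synthetic qualities
are a constant), and no mismatch-tolerant trimming is attempted. Reads whose
insert is empty are adaptor dimers and are discarded. "Junk / low
complexity" is a fixed rule: any non-ACGT(U) character, any single
nucleotide at ≥ 80 % of the tag, or a homopolymer run ≥ 10. The 80 %/10
constants are package choices — there is no community standard for this
filter — and both ends of the 18–26 nt retention window are inclusive.
Contaminant-family assignment is exact substring matching against
user-supplied family references on either strand, with the fixed precedence
rRNA > tRNA > snRNA > snoRNA > mRNA > other so every tag receives exactly
one category. U is normalized to T on input; all internal sequence space is
the uppercase DNA alphabet.

## Classification cascade

Alignment to precursors is ungapped: every offset is scanned, substitutions
are counted, at most one mismatch is allowed, and when the tag overlaps an
annotated mature arm (≥ 50 % of the tag) both end shifts must stay within
the end-variation window (default ± 4 nt; the window size is configurable
because isomiR end-variation has no canonical bound). Best alignment =
fewest mismatches, ties to the smallest offset. Tags on the unannotated
side of a precursor are arm variants, labelled p5/p3 by which side of the
precursor midpoint they fall on. Genome placement of remaining tags is
exact-match search of both strands — equivalent to a BLAST at 100 %
identity for 18–26-mers, without E-value semantics — and only the first hit
is used (multi-mapping resolution is out of scope). Known-tier calls merge
isomiR tag counts into the annotated mature sequence; arm-variant and
conserved calls group per (precursor, arm).

Candidate precursor windows take `flank = 100` nt (comfortably above the
50-nt minimum hairpin length) on one side of the mature locus, in two
arrangements (mature on the 3' arm vs on the 5' arm), strand-corrected and
clipped at contig bounds.

## Energy model and folding

The folder is a Zuker-style interval dynamic program over a simplified
nearest-neighbor model:

* a 6×6 stacking table over CG/GC/GU/UG/AU/UA pairs, with magnitudes on the
  usual kcal/mol scale (GC-rich stacks ≈ −3.3, AU/GU ≈ −1, one mildly
  destabilizing GU-on-UG entry);
* logarithmic destabilization for loops: hairpin 5.4 + 1.6·ln(n/3),
  bulge 3.8 + 1.6·ln(n), internal 4.1 + 1.6·ln(n/2) (n = total unpaired nt);
* a linear multibranch model (close 4.6, +0.4 per branch, +0.1 per unpaired
  nt), minimum hairpin loop 3, interior loops capped at 30 nt per side,
  exterior bases free, no dangles or terminal-mismatch terms.

The model is *not* Turner-complete and its energies are not comparable to
full RNAfold values; the screen only consumes a −15 kcal/mol gate, for which
the scale is adequate. Tie-breaking: among equal-energy optima the DP
prefers more pairs (an additive 10⁻⁴ kcal/mol/pair bias, far below the 0.1
table granularity); remaining ties are resolved by a fixed traceback order
that prefers pairing the leftmost base. This yields fully deterministic,
platform-independent structures but is not a proven global lexicographic
minimum over dot-brackets — determinism, not a particular canonical form,
is the requirement. A `pair_count` mode (every pair −1, loops free) turns
the same machinery into a Nussinov maximum-matching fold whose optimum is
verified against exhaustive enumeration in the tests, and an independent
structure-energy evaluator (loop decomposition of an explicit pair table)
cross-checks the nearest-neighbor DP optimum on short sequences.

## Hairpin metrics and criteria

Structures are segmented into a single stem-loop: the stem-loop with the
most pairs is annotated (sibling helices in the genomic flank are ignored),
and any multibranch *inside* that component rejects the candidate as a
non-hairpin. Vocabulary used by the screen, fixed and configurable:

* a **bulge** is one unpaired interruption between consecutive stem pairs,
  its size the total unpaired nt on both strands;
* **biased** means all unpaired nt of that interruption lie on one strand;
* **errors in the mature region** are its unpaired nucleotides (in nested
  structures mismatches and bulged bases are both simply unpaired);
* **hairpin length** is outermost pair to its partner, inclusive — unpaired
  flanking tails are excluded;
* **percent of mature in the stem** counts mature nt between the outer pair
  and the terminal loop (paired or inside stem bulges).

All eleven thresholds are compared inclusively, exactly as printed (≤ 12,
≥ 16, ≤ −15, ≥ 50, ≤ 20, ≤ 8, ≤ 4, ≤ 2, ≤ 7, ≥ 12, ≥ 80), with no
short-circuiting, so a verdict lists every failing criterion. Of a locus's
two windows the passing one wins; ties go to lower free energy, then fewer
failures. Refinement drops windows overlapping known precursor loci on the
same strand (antisense overlap does not share a precursor), deduplicates
identical (mature sequence, count vector) candidates keeping the
lowest-energy precursor, and requires ≥ 100 counts in **every** replicate of
at least one group. The count rule is applied to conserved-novel and novel
tiers only, not to known miRNAs.

## Differential expression

Library-size normalization is CPM — the minimal faithful reading of
"normalized by library size". The test is a two-sided pooled-variance
Student's t on normalized counts without log transform (a Welch variant is
available behind a flag); no multiple-testing correction is applied by
default because the modeled screen uses raw p ≤ 0.05 (BH-FDR is behind a
flag). Zero-variance features with equal means get p = 1; a zero baseline
mean with nonzero treatment mean reports an infinite fold change and a
flagged-undefined log2 FC. Significance is p ≤ α inclusive; the fold-change
gates (> 2, < 1/2) are strict, mirroring how volcano-plot gates are drawn.

## Synthetic study

The generator is the package's study-conditions definition, not a tuning
surface. Defaults: 30 known + 8 conserved + 6 novel + 4 decoy loci on a
60 kb genome, 3 + 3 replicates of 30,000 reads, mature lengths drawn from a
categorical law with a 0.45 mass at 22 nt inside 18–26 nt, abundances
log-normal(0, 2) scaled to the library (so a few miRNAs dominate the
library, as real small RNA libraries do), negative-binomial replicate
counts with dispersion α = 0.1 (var = μ + αμ², the edgeR/DESeq convention),
15 % of miRNAs spiked alternately up/down 4-fold in IIIb, 30 % contaminant
reads, 0.1 % substitution errors. Hairpin loci are built directly as
arm + 8-nt loop + reverse-complement arm from a GC-biased alphabet, which
guarantees deep stems; novel loci are additionally verified against the
11-criterion screen at construction (with bounded resampling), and decoy
loci get their arm shuffled and re-shuffled until the screen rejects them —
shuffling alone does not reliably prevent 12 pairable bp, so the explicit
check is part of the construction. Planted novel and decoy loci are floored
at a mean abundance of 600 so that the ≥ 100-count refinement rule tests
structure, not sampling noise. Every output is a pure function of the seed.

What the synthetic data does **not** emulate: instrument error profiles and
quality scores, ligation bias, multi-mapping repeat structure, isomiR end
heterogeneity in the reads themselves, and real genomic sequence
composition. Passing the end-to-end recovery tests therefore demonstrates
the pipeline's internal consistency — that its stages implement their rules
exactly and compose correctly — not field performance on real libraries.

A note on power: with dispersion 0.1 the per-feature CV of the counts is
≈ 0.32, and a 3 vs 3 pooled t-test at α = 0.05 detects a true 4-fold change
with roughly 85–90 % probability per feature. Recovery of the spiked set in
any single study realization is therefore high but not certain; the shipped
study seed is fixed and reported as-is.

## Target prediction and enrichment

The two predictors are simplified, documented stand-ins, not
reimplementations of any published tool, and their scores are not comparable
to those tools' outputs; only the per-transcript intersection is consumed.
The seed scanner classifies canonical sites from the reverse complement of
miRNA positions 2–7 plus the m8/A1 flanks. The complementarity aligner is a
Smith-Waterman local alignment of the reverse-complemented miRNA (match +5,
G:U +2, mismatch −3, gap −8, miRNA positions 2–8 doubled) gated at score
≥ 80 and implied-duplex stacking energy ≤ −14 kcal/mol; the weights are
configurable constants. Over-representation is an upper-tail hypergeometric
test against a user-supplied term→gene map (p ≤ 0.05), with no ontology
download or term-network post-processing.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; emitted GFF3 is 1-based
inclusive. Tables are UTF-8 TSV with mandatory headers. Folding accepts
10–400 nt; empty FASTQs, empty tag lists, zero-count matrices and all-zero
histogram inputs are valid and produce empty-but-well-formed outputs; a
zero-total sample is an error naming the sample. The pipeline is a single
sequential process; re-running any stage with the same configuration and
seed reproduces byte-identical files (sha256 recorded in the run manifest).

## Known limitations

The energy model's absolute energies are approximate; criteria consuming
them (the −15 kcal/mol gate) were designed for that scale, but structures
near the gate may fold differently under Turner-complete parameters. The
genome search reports first-best placements only. The arm-variant p5/p3
call uses the precursor midpoint, not the folded structure. The ORA universe
is whatever transcript set the caller supplies — no attempt is made to model
annotation bias.
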