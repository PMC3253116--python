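# Methods

## Problem and scope

`strandtile` analyzes strand-specific tiling-array data of the kind used to
map antisense transcription in fission yeast: 25-nt probes tile both genome
strands at a regular pitch, an RNA hybridization is measured per condition,
and a genomic-DNA (gDNA) hybridization of the same array design provides a
per-probe reference at constant copy number. The pipeline converts raw probe
fluorescence into background-anchored log2 expression, partitions each
strand into constant-mean segments, interprets segments against gene
annotation (sense / antisense / non-annotated), calls antisense RNAs,
computes per-gene sense and antisense averages, and runs the downstream
gene-group statistics and motif analyses. A synthetic-data generator
provides ground-truth test beds; it is first-class, tested code.

Coordinates are 0-based half-open internally (GFF3 converted on read/write).
A probe assigned strand *s* reports RNA transcribed *from* strand *s* —
sense signal for genes annotated on *s*. Array vendors are inconsistent
about whether a "strand" label means probe sequence or target RNA; we fix
this convention once and apply it identically in the simulator and the
quantification, which is what the analysis requires.

## Normalization

For unique probes p and RNA sample c:

    r_pc = log2(RNA_pc / gDNA_p),    output_pc = r_pc − b_c,

with b_c the median of r_pc over uniquely-mapping probes whose 25-nt
footprint overlaps no annotated CDS on either strand. Dividing by the gDNA
channel cancels the multiplicative probe effect; the median non-CDS offset
anchors background at 0. The median (not mean) is used for robustness to
residual transcription in unannotated regions. Only uniquely-mapping probes
are used anywhere downstream. The transform is exactly invariant to a
global rescaling of a sample's RNA channel and strictly increasing in raw
intensity. No cross-sample quantile normalization is applied; cross-sample
comparability rests on the shared gDNA reference, which is a divergence risk
on real scanner data with sample-dependent saturation.

Whether background correction should precede or follow the gDNA ratio is
not determined by the two-step description this follows; the order here
(ratio first, median offset second) is a documented choice, exact under the
multiplicative signal model below.

## Segmentation

Each (chromosome, strand) vector of log2 values is split into segments of
constant mean by dynamic programming over the residual sum of squares
(globally optimal for a given segment count, not greedy). The segment count
k maximizes the penalized Gaussian profile likelihood

    −(n/2)·log(RSS_k/n) − (λ/2)·k·log(n).

Parameters (all in `SegmentationModel`):

- `penalty` λ, default 4. Each added segment spends two effective
  parameters — a mean and a boundary position that is itself optimized over
  ~n candidates — so the BIC-consistent charge is 2·(log n)/2 per
  parameter, i.e. λ=4. Empirically λ=2 splits pure N(0,1) noise (n=100) in
  ~7% of replicates while λ=4 splits none of 100, with identical detection
  of a 1.5-sd step (82 vs 83 of 100).
- `min_probes`, default 4 (~100 nt at 25-nt pitch), suppresses
  single-probe artifacts.
- `max_segments`, default 60 per DP run. This is a capacity bound, not a
  model choice; when it binds, the DP merges the cheapest boundary (usually
  a short background dip), so it is sized with headroom for the densest
  chunk.
- `chunk_size` 3000 probes / `chunk_overlap` 300: exact DP is O(S·n²), so
  longer vectors are segmented in overlapping chunks and boundaries are
  reconciled in the overlap cores. Results carry an exactness flag
  (`is_exact`); chunked output is an approximation, though on the test beds
  it recovers the same boundaries.

Tie-breaks are deterministic: equal-RSS solutions prefer fewer segments
(enforced by clamping RSS at 1e-12 before the log, so the penalty decides),
and equal-cost boundary placements take the leftmost (first argmin).

## Segment interpretation and antisense calls

A segment's primary category is assigned by maximal reciprocal CDS overlap
(min of overlap/CDS-length and overlap/segment-length), requiring at least
50 nt of overlap, with ties preferring the same-strand (sense) assignment.
Antisense *calls* are made per (gene, segment) pair: every opposite-strand
CDS overlapped by ≥ 50 nt of a segment whose mean exceeds the calling
threshold (default 1.0, strict) yields one call. The pairwise rule matters
because one genomic region can be sense for one gene and antisense for its
convergent neighbor: a long 3'UTR-extension antisense typically segments
together with the neighbor's mRNA into a single constant-level segment that
covers both CDSs.

Origin classification of a call:

- `utr3_extension` — the antisense segment is continuous with a same-strand
  neighbor's transcript: it either overlaps that neighbor's CDS 5′-ward of
  the parent gene (the merged-segment case) or begins within
  `gap_tolerance` (default 100 nt) of the neighbor's 3' CDS end. The
  underlying data shows this continuity only qualitatively; 100 nt is a
  package default, exposed.
- `discrete_unit` — both flanking same-strand segments are low
  (mean ≤ the calling threshold) or absent.
- `unclassified` otherwise.

## Per-gene expression and splicing index

`sense_avg` / `antisense_avg` average, per strand, the unique probes whose
footprint lies fully inside the gene's CDS span (start codon through stop
codon, introns included — the genomic span, not the spliced transcript).
Genes without an eligible probe on a strand are flagged missing (NaN), never
zero, and excluded from medians and selections. An intron-excluding mode is
available (`include_intron_probes=False`) since the inclusion of intron
probes shapes the splicing-index interplay; the default includes them.

The splicing index is SI = mean(sense intron probes) − mean(sense exon
probes); SI < −1 log2 is labelled "spliced". A near-zero SI is ambiguous on
its own — an unspliced mRNA and a covering antisense RNA (which is itself
unspliced and dominates both intron and exon probes of the *opposite*
strand when the sense gene is silent) produce the same flat profile — so
the gene's antisense average is emitted alongside and the label reads
"unspliced_or_antisense_dominated".

## Gene-level statistics

All selections are pure functions of the per-gene table and the config, and
all cutoffs are strict inequalities:

- high-antisense / low-sense group: sense_avg < 1 and antisense_avg > 0.5
  (vegetative sample);
- differential sense: sense(A) − sense(B) > 1;
- new antisense: antisense(6 h)/antisense(veg) > 2, a linear ratio of the
  stored values; vegetative values ≤ 0 (possible on the background-anchored
  scale) are floored at 0.05 before dividing (exposed as `ratio_floor`);
  an optional exclusion set restricts the selection to non-meiotic genes;
- induction: strictly positive sense delta at either meiotic time point, no
  magnitude threshold;
- delta correlation: Pearson r between per-gene sense and antisense changes
  over complete pairs; fewer than 3 pairs or zero-variance deltas raise
  (never silently 0);
- enrichment: upper-tail hypergeometric P(X ≥ k), computed via the log-sf
  for tail stability. The annotated set (e.g. meiotic genes) is
  user-supplied; no ontology database is consulted. No multiple-testing
  correction is applied by default; Benjamini–Hochberg is available for
  users scoring many sets.

## Motif analyses

IUPAC scanning matches every position on both strands (minus-strand hits by
scanning the reverse-complement pattern; a hit's coordinate is its 5' base
on its own strand). Antisense-origin proximity reports the fraction of
calls whose 5' boundary lies within a window of any motif hit; because
"close" has no canonical distance, a sensitivity report over {200, 500,
1000} nt is emitted (default single-window analyses use 500 nt).

The common-k-mer search enumerates all 4^k words, counts the input
sequences containing each (optionally counting reverse-complement matches),
and attaches the background probability that the word would occur in *all*
m sequences. Containment probabilities are exact under an iid background:
an Aho–Corasick automaton of the word (and its reverse complement in
both-strand mode) is converted to a transfer matrix and powered to the
sequence length. This matters: for self-overlapping words the
independent-window approximation 1−(1−4^−k)^W is off by several percent
(P(contain "AA" in 10 nt) is 0.388 exactly vs 0.441 approximated); the
approximation remains available as `method="iid"`. This statistic is a
transparent replacement for EM-based motif discovery, not a reimplementation
of it; its p-values are not comparable to MEME E-values.

## Synthetic data

The generator lays out architecture "slots" along a random genome
(default 120 kb, 600 nt gaps) in shuffled order: constitutive mRNAs;
mid-meiotic genes that are sense-silent vegetatively under a covering
antisense RNA — discrete units or 3'UTR extensions of a convergent
neighbor — with sense induction and antisense decay over a meiotic time
course (abundances 0 → 0.4 → 1.2; antisense 0.35 → 0.15 → 0.05); a subset
derepressed in the fkh2 mei4 double mutant (sense 0.6); non-meiotic genes
gaining a covering antisense at 6 h (0.05 → 0.5) with reciprocal sense
repression; internal-bidirectional genes (truncated sense + divergent
antisense, ACGCTC planted at the internal start, full-length sense at 6 h);
intron genes in spliced (intron abundance 0) and unspliced states; and
exact two-fold sense changes for fold-recovery checks. GTAAAYA instances
are planted 20–150 nt upstream of meiotic sense promoters and of a
configurable exact fraction of antisense 5' starts.

Signal model: raw = (a_p·(A + bg) + opt)·ε, with a_p ~ lognormal(0, σ)
drawn once per probe (σ default 0.5; 1.0 in normalization stress tests),
bg = 0.1 nonspecific-hybridization background *subject to the probe
effect*, opt an affinity-free optical term (default 0), and ε lognormal
with unit mean and CV 0.2. The gDNA channel uses A = 1. Background is
placed inside the probe effect deliberately: nonspecific hybridization is
probe-dependent, and this is the regime in which ratio-to-gDNA
normalization is exactly correct, so the normalizer has a well-defined
target (with opt = 0, a transcript at abundance A lands exactly at
log2(1 + A/bg), putting expressed levels in ~0.5–5 where the 0.5/1.0
thresholds are meaningful). A probe counts as covered by a transcript at
≥ 1 nt footprint overlap, with no fractional weighting; segmentation
tolerance absorbs edge probes. The structure seed (genome, annotation,
truth) can be split from the noise seed.

No published noise magnitudes exist for this design; the defaults are
calibrated to reproduce qualitative structure only. The simulator omits
sequence-dependent affinity (affinities are iid lognormal),
cross-hybridization, optical/spatial artifacts, scanner saturation, and
replicate arrays — so passing recovery tests demonstrates the algorithms'
correctness under the stated model, not performance on real arrays.

## Evaluation conventions

Truth-based scoring of a run: per-probe truth labels are sample-aware
(sense/antisense only where transcription is actually present, from the
planted intervals); segment-category accuracy is scored over expressed
segments (mean > 0.5), counting a segment correct when its category is
among the truth labels held by ≥ 30% of its probes, since merged
3'UTR-extension segments legitimately carry both sense and antisense truth.
Origin accuracy counts an uncalled planted antisense as an error. The
planted delta-correlation recovery (ρ = −0.4) is evaluated at the gene-table
level with n = 2000 synthetic genes; a probe-level simulation of that size
would add nothing to the check while dominating runtime — the pipeline-level
correlation is evaluated separately on the default run.

Problem sizes used throughout (default 120 kb genome / ~9600 probes /
34 genes; 32–50 kb beds for repeated-seed studies) are chosen so every DP
is exact or at most two chunks and whole-suite runs stay interactive.

## Known limitations

- Chunked segmentation is approximate near chunk joins; exact mode is
  guaranteed only up to `chunk_size` probes per strand.
- The background-anchored scale places silent genes near 0 with noise on
  both sides; ratio-type selections therefore depend on `ratio_floor`.
- Origin classification assumes the annotation's CDS ends approximate 3'
  ends; genes with long annotated 3'UTRs would need `utr3_end` support in
  the adjacency rule.
- Supplementary-table ingestion expects one `<sample>_sense` /
  `<sample>_antisense` column pair per sample; published spreadsheets with
  other layouts need renaming on import.
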