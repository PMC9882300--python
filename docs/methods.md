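# Methods

## Overview

`pirnaquant` quantifies small-RNA sequencing libraries from *C. elegans*
with the read taxonomy used in piRNA-biogenesis studies: mature piRNAs
(21U-RNAs), capped piRNA precursors, 22G-RNA secondary siRNAs, miRNAs, and
structural-RNA degradation fragments. The pipeline is deliberately exact:
zero-mismatch alignment, rule-based classification, and closed-form
normalization, so every stage can be checked against an independent oracle
or a simulator's ground truth.

## Alignment

Reads are aligned to the genome requiring a perfect match, and *all*
perfect loci on both strands are reported (a k-mer-seeded exact-substring
index with full verification; reads shorter than the seed fall back to a
direct scan). With zero mismatches permitted there is only one alignment
stratum, so "best-stratum" semantics reduce to reporting perfect hits; we
enumerate every locus because the multi-mapper weight downstream is
1/n_loci and therefore needs the complete locus count. The strand of a
record is the strand whose 5'→3' sequence equals the read; a read matching
a palindromic site yields one record per strand and both count in n_loci.
Reads containing N never align. Unmappable reads are dropped and counted
in the run manifest.

## Overlap and coordinates

All internal coordinates are 0-based, half-open; GFF3 (1-based inclusive)
and SAM (1-based) are converted only at I/O boundaries. Read–feature
overlap requires at least one shared base (the `bedtools intersect`
default); orientation is sense iff alignment and feature strands agree,
and containment is flagged when the alignment lies fully inside the
feature. Adjacent half-open intervals [a,b) and [b,c) do not overlap.

## Classification rules

Each aligned read receives exactly one class, the highest-priority class
it qualifies for at any of its loci:

1. **structural_sense** — sense overlap with rRNA/tRNA/snoRNA/snRNA.
   These are treated as degradation products; they rank first because they
   are excluded from the normalization denominator. We include snRNA in
   the structural set (it is a structural locus class in the annotation
   universe), alongside the conventional rRNA/tRNA/snoRNA trio.
2. **pirna_precursor** — sense read whose 5' end lies exactly 2 nt
   upstream of a piRNA locus' mature 5' end (in the locus strand frame)
   and which contains the full mature sequence; 3' readthrough is allowed.
   Because alignment is exact, the 2-nt overhang necessarily matches the
   genomic upstream dinucleotide. Precursor outranks mature: a precursor
   read always also overlaps the piRNA feature and would otherwise never
   classify.
3. **pirna_mature / mirna_mature** — sense read whose alignment interval
   equals the annotated mature interval exactly. Any overhang or
   truncation disqualifies.
4. **twenty_two_g** — 21–23 nt (inclusive) read whose first sequenced base
   is G (a property of the RNA, tested on the read, not the genome),
   aligned antisense to a protein-coding gene, pseudogene, or transposon.
5. **coding_sense** — sense overlap with a protein-coding gene.
6. **other** — everything else that aligned. Reads antisense to structural
   RNAs or sense to transposons fall here / to coding_sense; no claim is
   made that this matches any particular upstream convention.

Length windows are inclusive: 17–40 nt for standard small-RNA libraries,
17–100 nt for CapSeq. A multi-mapping read whose loci imply different
classes takes the highest-priority class and distributes weight 1/n_loci
to each qualifying locus of that class only — deterministic and
conservative.

## Counting and normalization

Each read contributes 1 to total mapped reads and weight 1/n_loci per
qualifying locus of its winning class, so a read whose loci all carry its
class contributes exactly 1.0. RPM normalization excludes structural-sense
reads from the denominator:

    RPM(x) = 1e6 · count(x) / (total_mapped − structural_sense)

Degenerate libraries (empty, or all-structural) set an explicit flag
instead of dividing by zero.

Fold changes are log2((treatment_RPM + pc) / (control_RPM + pc)) with
pseudocount pc = 0.1 RPM by default — small enough not to dominate
moderately expressed loci, large enough to keep log2fc finite; it is
configurable everywhere it appears. Groupings: per feature, per class,
per (class, gene-class), per (class, piRNA type), and per-gene 22G counts.

## Comparisons and derived analyses

* **Gene-class comparison** (CSR-1 vs WAGO 22G targets): two-sided
  Mann-Whitney rank-sum on per-gene log2 fold changes. Chosen because it
  is distribution-free and standard for fold-change vectors; with all
  values tied the test returns the null center and p = 1. Calibration is
  checked with count-level null replicates (shared log-normal per-gene
  means, independent Poisson counts, equal folds): simulating read-level
  libraries hundreds of times would test the same statistic at far greater
  cost without exercising anything new, so calibration is a property of
  the counting-and-testing stages alone.
* **SNPC-4 dependency stratification**: the dependent set is the quantile
  (default 0.25, configurable — the defining fraction is an analysis
  choice) of piRNA loci with the lowest knockdown fold changes of their
  mature reads; boundary ties break by locus id.
* **Precursor histogram**: lengths of *unique* precursor sequences (a
  molecule seen 100× counts once); peaks are strict local maxima (count
  exceeds both neighboring lengths) above a configurable floor — the
  simplest deterministic peak rule.
* **CapSeq enrichment metric**: (precursor/mature RPM ratio in CapSeq) ÷
  (same ratio in the standard library). Undefined when the standard ratio
  cannot be formed; an ideal cap filter leaves no mature reads at all, in
  which case the unsmoothed metric is +inf and a pseudocounted variant
  provides a finite value for reporting.
* **Reporter scoring**: percent of scored animals with an activated
  reporter; a treatment is called positive strictly above 20% (control
  treatments occasionally show spurious activation but never exceed 20%).

## Synthetic data

The generator emulates the annotation universe and read species the
pipeline is designed for, with everything deterministic given a seed.

**Genome/annotation.** Random-sequence chromosomes (default 3 × 30 kb)
carry non-overlapping features: type I piRNA loci (21-nt mature starting
with T on the annotated strand; a fixed 8-nt placeholder "Ruby motif"
embedded 2–10 nt upstream plus an annotation tag — type labels, not motif
discovery, drive the analysis), type II piRNA loci (no motif), miRNA loci
(22-nt mature), structural loci (rRNA/tRNA/snoRNA/snRNA), protein-coding
genes labelled csr1_target/wago_target/none (fractions 0.4/0.4/0.2), and
transposons. Mature sequences are embedded verbatim at their coordinates.
Each locus draws a log-normal relative abundance (σ = 1, spanning roughly
two orders of magnitude, as real piRNA loci do) at genome-simulation time,
so libraries simulated under different seeds share per-locus expression.
Placement failure (footprint exceeding the genome) raises an error naming
the offending locus class.

**Libraries.** Reads are drawn from a categorical mixture over
(class, locus): base class weights × within-class abundance × condition
multipliers, renormalized. The default mix (structural 0.30, miRNA 0.35,
22G 0.12, mature piRNA 0.04, precursor 0.01, coding-sense fragments 0.18)
reflects whole-animal libraries where structural degradation and miRNAs
dominate and piRNA species are minor components. Mature piRNA/miRNA reads
equal the locus mature sequence exactly; precursors start exactly 2 nt
upstream and read through by an offset drawn from modes {2, 18, 38} nt
(weights 0.5/0.3/0.2), yielding 25/41/61-nt precursors of a 21-nt mature —
a simulation choice giving the histogram stage multimodal truth, not a
reproduced measurement; 22Gs are 21–23-nt 5'G reads antisense to
coding/transposon loci (anchor positions are enumerated so eligibility is
checked, with an error if a target has none); structural/coding fragments
are sense sub-reads of 20–35 nt. Fragment lengths start at 20 nt so that
chance second alignments of short random fragments are negligible and the
noise-free truth-recovery property is exact. 5' chemistry follows the
species: precursors capped, 22Gs triphosphorylated, everything else
monophosphorylated; CapSeq enrichment is an order-preserving filter
keeping exactly the capped reads. No sequencing-error, quality,
ligation-bias, or PCR-duplication model is included — the aligner permits
zero mismatches, so errors would only shrink libraries.

**What passing tests do and do not show.** On these libraries
classification is exactly recoverable (precision = recall = 1), which
validates the *rules*, not robustness to real-data artifacts (untrimmed
adapters, sequencing errors, overlapping gene models, isomiRs), none of
which the generator produces.

## Validation scenarios and problem sizes

Scenario libraries are 100 000 reads (50 000 for CapSeq and
truth-recovery) — large enough that a 3σ binomial fluctuation of any
perturbed class is under ~2% while keeping a full scenario under half a
minute on one core.

Because library depth is fixed, the read mixture is compositional:
scaling one class down inflates every RPM by 1/(1 − Δ/NS), where Δ is the
removed mixture mass and NS the non-structural share. Scenario mixes are
therefore sized by a worst-case rule: the perturbed class' share is kept
small enough that this bias stays under ~5% *regardless of how abundance
splits across loci* (e.g. ints-1-like: 0.7·0.04/0.70 = 4%; npp-7-like 22G
share 0.05: ≤ 0.6·0.05/0.68 ≈ 4.4% even if one gene class held all 22G
abundance). The npp-7-like mix omits sense gene fragments so the per-gene
multipliers act on 22Gs alone. The snpc-4-like scenario instead uses a
piRNA-enriched mix (mature share 0.25) because locus-level stratification
needs per-locus depth (~100 expected reads per locus at 200 type I loci);
its rank-based recovery is insensitive to the compositional bias.

## Known limitations

* Exact-match alignment only: no mismatches, gaps, or spliced alignment.
* Flat gene models: no exon/intron structure or nested features.
* The class-priority order and the multi-class multi-mapper rule are
  package conventions where upstream practice is unstated.
* Adapter trimming is a minimal exact-prefix 3' clipper (≥8-nt match);
  simulated libraries are generated pre-trimmed.
* RPM fold changes carry the compositional bias described above; the
  package reports plain RPM ratios and does not attempt spike-in or
  median-ratio correction.
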