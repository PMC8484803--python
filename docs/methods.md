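# Methods

This note documents the models, conventions and design choices behind the
toolkit. It is written for users who want to know exactly what each
operation computes and what the synthetic cohorts used in the test suite
do and do not demonstrate.

## Coordinate model

All intervals in the internal data model are 1-based and fully closed
(the PLINK convention). Two intervals overlap if and only if they share
at least one base pair: `[100, 200]` and `[200, 300]` overlap at base
200, while the bookended pair `[100, 200]` / `[201, 300]` does not. This
single rule drives CNVR calling, gene annotation, interval comparison and
ROH incidence. UCSC gene tables are 0-based half-open on txStart; the
refGene reader is the only place a base shift (+1 on the start) occurs,
so no downstream code ever reasons about mixed conventions.

Chromosome labels are stored without a `chr` prefix. X, Y and MT are
retained but treated as non-autosomal: F_roh and ROH incidence operate on
autosomes only, and CNV cleaning drops calls on labels that are neither a
decimal autosome nor X/Y/MT (unplaced scaffolds and the like), counting
them in the cleaning report.

## CNV standardization and summaries

A copy-neutral call (cn = 2) is not a CNV; `clean_cnv` drops such rows
(and counts them) so the type logic downstream is strictly two-valued:
deletion for cn < 2, duplication for cn > 2. Copy numbers above 4 are
retained with their integer state rather than capped, preserving detail
for state-level summaries and colors. Cleaning is idempotent, and all
summary cross-tabulations are invariant to input row order.

Length groups are half-open bins `[b_i, b_{i+1})`. The default CNV
breaks are 0, 100 kb, 500 kb, 1 Mb, 5 Mb, ∞ — conventional SNP-array CNV
size classes, overridable everywhere a summary is computed.

## CNVR calling

CNVRs are the connected components of the pairwise ≥1 bp overlap graph
over all samples' CNVs. The implementation is a per-chromosome sweep
over start-sorted intervals (merge while `start ≤ current_end`), which is
O(n log n); the test suite checks it against an independent
connected-components oracle on random interval sets. Region type is
Deletion / Duplication / Mixed, Mixed meaning the members include both a
deletion and a duplication. `n_samples` counts distinct carriers of any
type; per-type member counts are also reported, but a single
distinct-sample count is used for frequency thresholding.

High-frequency selection keeps regions with `n_samples / sample_size ≥
threshold`; the default threshold is 0.05, the conventional common-variant
cutoff, and `sample_size` is an explicit argument because the CNV table
usually underrepresents the genotyped cohort (samples without calls).

## Gene annotation and gene frequency

A gene is annotated to an interval iff they share ≥1 bp on the same
chromosome; strand is ignored. Gene frequency is deliberately computed
from per-sample CNV annotations rather than from CNVRs: annotating genes
at the region level gives rare CNVs carried by one or two samples the
apparent weight of the whole region. A sample carrying two disjoint CNVs
over the same gene counts once (distinct-carrier counting). Gene symbols
match case-sensitively, with case-insensitive fuzzy suggestions on a
miss, since symbol capitalization is species-convention-dependent.

## Interval comparison

`compare_interval` emits every ≥1 bp overlapping pair with the overlap
size and the fraction of each interval covered. Two comparison levels:
population (regions only) and individual (the same sample must carry
both calls). Because one long interval can overlap several short ones, a
single "overlap count" is ambiguous; reports carry A-anchored and
B-anchored overlapping counts, per-interval multiplicity histograms, and
a merged-region count (connected components of the bipartite overlap
graph). Type-mismatched overlaps (deletion vs duplication) are counted
as overlaps and exposed in an optional 2×2 stratification.

## Map conversion and liftover

Two maps of the same chip are matched by marker name (a full outer
join); each marker is classed same_chr / chr_changed / missing_in_target
/ missing_in_default. Zero shared names is a hard error — conversion is
meaningful only within one chip. Liftover is SNP-anchored, never
interpolated: an interval's converted span is the [min, max] of the
target positions of the markers inside it. The target chromosome is the
modal chromosome of those markers, with ties broken toward the default
chromosome, else lexicographically. If more than 10% of in-interval
markers map off the modal chromosome (configurable), conversion fails
with `snps_split_across_chromosomes`; a tolerated minority is dropped
and counted. Reported lengths are marker-anchored spans on *both*
assemblies, so `length_delta` isolates what the assembly change did to
the region and is exactly zero under a self-map or a rigid shift.
`order_inverted` flags intervals whose marker order is not monotone
between assemblies.

## ROH analysis

F_roh = (Σ L_roh) / (Σ L_auto): the summed autosomal ROH length of an
individual over the total autosome length. When true assembly lengths
are not supplied, Σ L_auto defaults to the chip-covered span per
autosome (max − min marker position + 1) from the supplied map — a
reproducible denominator that requires no external genome metadata.
Per-length-group components use the disjoint bins 0–2, 2–4, 4–8, 8–16,
>16 Mb by default (standard ROH classes, reflecting inbreeding at
different time depths) and sum exactly to the total.

High-frequency ROH detection is anchored on map markers, not fixed-bp
windows: marker density varies along the chromosome and strongly affects
ROH inference, so carrier frequency is counted at each marker (distinct
individuals with ≥1 spanning ROH) and maximal runs of consecutive
markers at or above the threshold (default 0.3, configurable) become
regions. The frequency denominator is every individual present in the
`.hom` file, overridable with the full genotyped cohort size.

## Haplotypes

Over a SNP window (located with `closer_snp`: all in-region markers, or
the two flanking markers when the region contains none), haplotype
frequency is count / 2N over the 2N haploid allele strings and diplotype
frequency is count / N over unordered haplotype pairs — unordered
because statistical phasing does not identify parent of origin.
Haplotype ids H1, H2, … are assigned by descending count with
lexicographic tie-breaks. Missing alleles are an error, not imputed: the
reader targets complete phased output (Beagle-style `0|1` GT).

## Synthetic cohorts

The fixture generator emulates the input side of a SNP-array study: a
CNV cohort of 100 samples on 5 autosomes of 50 Mb, a ROH cohort of 50
individuals, 10,000-marker maps, a 200-gene reference list with 30%
duplicated transcript rows, and 200 phased diploid genotypes over a
5-SNP window. Planted structure is exact by construction:

* carriers are sampled *without replacement*, so a fraction f of n
  samples yields exactly round(f·n) carriers (default planted CNVR: 20%
  of the cohort, cn = 1, with a gene placed inside the region);
* background CNVs are private (one sample each) and placed in disjoint
  genome slots that avoid the planted region, so every background CNVR
  has exactly one carrier and the planted region is the only common one;
* background ROH covers 5% of the genome per individual (1–3 Mb
  segments at random positions), far below the 0.3 frequency threshold,
  while the planted 2 Mb segment is shared by 40% of individuals;
* the target map applies disjoint marker perturbation classes (3%
  dropped, 1% chromosome-moved, 5% position-shifted by default) and an
  optional uniform offset for rigid-shift liftover checks;
* the phased haplotypes are drawn from a planted {0.6, 0.3, 0.1}
  distribution and every individual draw is recorded, so recovered
  counts are ledger equalities, not statistical approximations.

The truth ledger (`truth.json`) records carriers, per-individual ROH
totals, perturbation assignments and haplotype draws; planted-recovery
tests read only the ledger. The same seed reproduces every file
byte-for-byte.

What these cohorts do **not** emulate: linkage disequilibrium, uneven
real-chip marker density, chip-specific clustering artifacts, genotyping
error, or overlapping background CNVs between samples. Passing tests
therefore demonstrate the correctness of the interval algebra, counting
and frequency logic under controlled conditions — not detection accuracy
on real intensity data, which is upstream of this toolkit entirely.

## Numerical and degenerate-input choices

* Frequencies are ratios of integer counts; sums over a frequency table
  equal 1 exactly rather than to rounding error.
* Sorting is stable (mergesort) everywhere ordering is user-visible, so
  ties are deterministic.
* Empty inputs yield empty outputs with warnings where the empty case is
  legitimate (an empty CNV file, a region without intervals) and errors
  where it signals misuse (summarizing an empty table, converting
  through an empty map).
* Chromosomes with fewer than two markers get an undefined mean gap and
  a degenerate flag in density tables rather than a division by zero.

## Problem sizes in the test suite

Oracle comparisons use sizes where the quadratic reference is
comfortable: 1,000 intervals × 20 seeds for CNVR calling, 500 × 500 for
pair comparison, 300 genes × 100 intervals for annotation. The planted
cohorts use the defaults above. These sizes were chosen as the smallest
at which the combinatorics are non-trivial (multi-member regions, split
and merged overlaps, minority chromosomes) while keeping the whole suite
fast on one CPU.

## Known limitations

* Raw intensity (BAF/LRR) data is out of scope, so intensity-level
  visual QC of a CNVR is not provided.
* VCF input must be bi-allelic and fully phased; bgzip/tabix-indexed
  files are read by pysam but no index-dependent random access is used.
* No reciprocal-overlap CNVR definition (≥1 bp only) and no
  association testing — dedicated tools exist for both.
* Liftover requires both maps to come from the same chip; chain-file
  (alignment-based) liftover is intentionally not implemented.
* ROH detection and phasing are upstream (PLINK, Beagle); the toolkit
  starts from their outputs.
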