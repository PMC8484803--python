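# cnvroh

Post-analysis toolkit for copy number variants (CNV), copy number
variation regions (CNVR) and runs of homozygosity (ROH) detected from
SNP-array genotyping data.

Detecting CNVs and ROH from SNP chips is well served by tools like
PennCNV, CNVPartition and PLINK — but what comes *after* detection
(standardizing call tables, merging calls into population-level regions,
annotating genes with honest frequencies, comparing studies, converting
coordinates between genome assemblies, computing inbreeding
coefficients, extracting haplotypes) is usually stitched together from
ad-hoc scripts. This package provides that post-analysis layer as a
tested Python library with a thin CLI, for researchers working on humans
or diploid livestock species.

It also bakes in guards against common analysis pitfalls:

* gene frequencies are computed from per-sample CNVs, never from CNVRs,
  so genes hit by one rare call don't inherit the weight of a region;
* interval sets are compared at both the population level and the
  individual level (same sample must carry both calls);
* overlap counts are multiplicity-aware — one long interval overlapping
  several short ones is not "one overlap";
* assembly conversion reports length changes, order inversions and
  markers that moved chromosome, instead of silently assuming a clean
  mapping.

## The core definitions

* **CNVR**: the union of a maximal set of CNVs, from any samples,
  chained by pairwise overlap of ≥1 bp (closed 1-based intervals).
  Typed Deletion / Duplication / Mixed, where Mixed means both deletions
  and duplications occur among the members.
* **Carrier frequency** of a CNVR or gene: distinct carrier samples
  divided by cohort size; regions with frequency ≥ a threshold (default
  0.05) are "common".
* **Inbreeding coefficient**: F_roh = (Σ L_roh) / (Σ L_auto), the total
  autosomal ROH length over the total autosome length, reported in
  total and per ROH length class (0–2, 2–4, 4–8, 8–16, >16 Mb).
* **High-frequency ROH region**: a maximal run of consecutive map
  markers whose ROH carrier frequency meets a threshold (default 0.3).
* **Haplotype / diplotype frequency** over a SNP window: counts over the
  2N haploid allele strings, and over the N unordered haplotype pairs.

## Worked example

Generate a synthetic cohort (100 samples, a CNV region planted into 20%
of them over private background calls) and run the post-analysis:

```python
from cnvroh.fixtures import FixtureConfig, gen_cohort
from cnvroh import formats_io, clean_cnv, call_cnvr, high_freq_cnvr
from cnvroh.annotation import annotate_intervals, gene_frequency

ledger = gen_cohort(FixtureConfig(seed=1), "demo")
parsed = formats_io.read_cnv(ledger["files"]["penncnv"], dialect="penncnv")
clean, report = clean_cnv(parsed.records)
print(f"{len(clean)} CNVs kept ({report.dropped_cn2} copy-neutral dropped)")

cnvr, membership = call_cnvr(clean)
print(f"{len(cnvr)} CNVRs called from {len(clean)} CNVs")

common = high_freq_cnvr(cnvr, sample_size=100, common_cnv_threshold=0.1)
print(common[["cnvr_id", "chrom", "start", "end", "n_cnv", "n_samples",
              "cnvr_type", "freq"]])

genes = formats_io.read_refgene(ledger["files"]["refgene"])
freq = gene_frequency(annotate_intervals(clean, genes), sample_size=100)
print(freq.head(3))
```

Output:

```
320 CNVs kept (0 copy-neutral dropped)
301 CNVRs called from 320 CNVs
     cnvr_id chrom     start       end  n_cnv  n_samples cnvr_type  freq
0  CNVR_1_10     1  10000001  10200000     20         20  Deletion   0.2
    gene_name  n_samples  n_cnv chrom  fraction_of_cohort
0  GENE_PLANT         20     20     1                0.20
1    GENE0023          3      3     2                0.03
2    GENE0001          2      2     5                0.02
```

The 301 CNVRs are the 300 single-carrier background regions plus the
planted one; only the planted region (20/100 carriers, frequency 0.2)
passes the 0.1 common-CNV threshold, and the gene planted inside it tops
the frequency list with exactly its 20 carrier samples.

The same operations are available from the shell:

```sh
cnvroh fixtures --seed 1 --out demo
cnvroh cnv --input demo/cnv.penncnv.txt --sample-size 100 \
    --refgene demo/refgene.txt --out demo_results
cnvroh roh --hom demo/plink.hom --map demo/default.map --out demo_roh
cnvroh map-convert --default demo/default.map --target demo/target.map \
    --out-prefix demo_conv
cnvroh haplotype --vcf demo/phased.vcf --region 2:1000000-1040000 \
    --out-prefix demo_hap
```

ROH detection itself (PLINK `--homozyg`) and phasing (Beagle) are
upstream steps; this toolkit consumes their `.hom` and phased-VCF
outputs.

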