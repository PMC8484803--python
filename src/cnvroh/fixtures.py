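"""Seeded synthetic cohorts with planted, exactly recoverable structure.

The generator emits every input dialect the toolkit reads — PennCNV raw
CNV calls, a CNVPartition CSV, a PLINK ``.hom`` ROH table, two PLINK
``.map`` SNP maps differing by controlled perturbations, a refGene-style
gene list, and a phased VCF — together with a truth ledger recording what
was planted: CNVR/ROH carrier sets, per-individual ROH totals, haplotype
counts and per-marker map perturbations. Planted-recovery tests read only
the ledger.

Design notes
------------
* Carrier sets are drawn *without replacement*, so a carrier fraction f
  over n samples yields exactly ``round(f * n)`` carriers.
* Background CNVs are private (one random sample each) and are placed in
  disjoint genome slots that avoid the planted regions, so no background
  CNVR ever spans more than one sample and the planted region is the only
  common one.
* Same seed, same config => byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cnvroh import formats_io

_BASES = np.array(list("ACGT"))

# PennCNV hidden-state label per copy number, as in its raw output.
_CN_STATE = {0: 1, 1: 2, 3: 5, 4: 6}


@dataclass
class PlantedCnvr:
    """A CNV stamped identically into a fixed fraction of the cohort."""

    chrom: str = "1"
    start: int = 10_000_001
    end: int = 10_200_000
    carrier_fraction: float = 0.2
    cn: int = 1
    gene_name: str | None = "GENE_PLANT"   # gene planted inside the region


@dataclass
class PlantedRoh:
    """A segment homozygous-in-ROH for a fixed fraction of individuals."""

    chrom: str = "2"
    start: int = 20_000_001
    end: int = 22_000_000
    carrier_fraction: float = 0.4


@dataclass
class FixtureConfig:
    seed: int = 0
    n_samples: int = 100               # CNV cohort size
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    n_snps: int = 10_000               # markers per map, split across chromosomes

    # CNV background: private calls, one random sample each
    n_background_cnv_per_sample: int = 3
    background_cnv_length: tuple[int, int] = (10_000, 50_000)
    planted_cnvr: PlantedCnvr = field(default_factory=PlantedCnvr)

    # ROH cohort
    n_roh_samples: int = 50
    planted_roh: PlantedRoh = field(default_factory=PlantedRoh)
    background_roh_genome_fraction: float = 0.05
    background_roh_length: tuple[int, int] = (1_000_000, 3_000_000)

    # phased genotypes
    n_hap_samples: int = 200
    n_hap_snps: int = 5
    haplotype_freqs: tuple[float, ...] = (0.6, 0.3, 0.1)

    # target-map perturbation rates
    map_missing_rate: float = 0.03
    map_chr_change_rate: float = 0.01
    map_shift_rate: float = 0.05
    map_shift_range: tuple[int, int] = (1_000, 100_000)
    map_uniform_shift_bp: int = 0      # added to every target position

    # gene list
    n_genes: int = 200
    gene_duplicate_fraction: float = 0.3

    def validate(self) -> None:
        for planted in (self.planted_cnvr, self.planted_roh):
            if planted.end > self.chrom_length_bp:
                raise ValueError(
                    f"planted region {planted} exceeds chromosome length "
                    f"{self.chrom_length_bp}")
            if not (0 <= planted.carrier_fraction <= 1):
                raise ValueError("carrier fractions must be in [0, 1]")
        if abs(sum(self.haplotype_freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype_freqs must sum to 1")

    @property
    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    @property
    def autosome_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chromosomes}


def _sample_ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def _exact_carriers(rng, ids: list[str], fraction: float) -> list[str]:
    k = round(fraction * len(ids))
    return sorted(rng.choice(ids, size=k, replace=False).tolist())


def _background_slots(config: FixtureConfig, avoid: list[tuple[str, int, int]]
                      ) -> list[tuple[str, int]]:
    """Disjoint slot starts across the genome, skipping ``avoid`` regions."""
    width = config.background_cnv_length[1] + 10_000
    slots = []
    for chrom in config.chromosomes:
        n_slots = config.chrom_length_bp // width
        for i in range(n_slots):
            s = i * width + 1
            e = s + width - 1
            if any(c == chrom and s <= ae and e >= as_
                   for c, as_, ae in avoid):
                continue
            slots.append((chrom, s))
    return slots


def gen_cnv(config: FixtureConfig, rng) -> tuple[pd.DataFrame, dict]:
    """Per-sample CNV calls: one planted common CNVR plus private
    background calls in disjoint slots."""
    ids = _sample_ids("S", config.n_samples)
    p = config.planted_cnvr
    carriers = _exact_carriers(rng, ids, p.carrier_fraction)
    rows = []
    for sid in carriers:
        rows.append({"sample_id": sid, "chrom": p.chrom, "start": p.start,
                     "end": p.end, "cn": p.cn})
    avoid = [(p.chrom, p.start, p.end)]
    slots = _background_slots(config, avoid)
    n_bg = config.n_background_cnv_per_sample * config.n_samples
    if n_bg > len(slots):
        raise ValueError(f"need {n_bg} background slots, only {len(slots)} available")
    chosen = rng.choice(len(slots), size=n_bg, replace=False)
    lmin, lmax = config.background_cnv_length
    cn_states = np.array([0, 1, 3, 4])
    n_del = len(carriers) if p.cn < 2 else 0
    n_dup = len(carriers) - n_del
    for j, slot_i in enumerate(chosen):
        chrom, slot_start = slots[slot_i]
        length = int(rng.integers(lmin, lmax + 1))
        offset = int(rng.integers(0, lmax - length + 1))
        cn = int(rng.choice(cn_states))
        sid = ids[j % config.n_samples]
        rows.append({"sample_id": sid, "chrom": chrom,
                     "start": slot_start + offset,
                     "end": slot_start + offset + length - 1, "cn": cn})
        if cn < 2:
            n_del += 1
        else:
            n_dup += 1
    df = pd.DataFrame(rows)
    ledger = {
        "samples": ids,
        "planted_region": {"chrom": p.chrom, "start": p.start, "end": p.end,
                           "cn": p.cn},
        "planted_carriers": carriers,
        "n_background": int(n_bg),
        "n_del": int(n_del),
        "n_dup": int(n_dup),
        "gene_name": p.gene_name,
        "gene_carriers": carriers if p.gene_name else [],
    }
    return df, ledger


def write_penncnv(cnv: pd.DataFrame, path) -> None:
    """Write CNV rows as PennCNV raw output lines."""
    with open(path, "w") as fh:
        for row in cnv.itertuples():
            length = row.end - row.start + 1
            numsnp = max(3, length // 5000)
            state = _CN_STATE.get(int(row.cn), 2)
            fh.write(
                f"chr{row.chrom}:{row.start}-{row.end}\tnumsnp={numsnp}\t"
                f"length={length:,}\tstate{state},cn={row.cn}\t{row.sample_id}\t"
                f"startsnp=SNP_{row.chrom}_A\tendsnp=SNP_{row.chrom}_B\n")


def write_cnvpartition(cnv: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "SampleID": cnv["sample_id"], "Chr": cnv["chrom"],
        "StartPosition": cnv["start"], "EndPosition": cnv["end"],
        "CopyNumber": cnv["cn"], "Confidence": 35.0,
    })
    out.to_csv(path, index=False)


def gen_roh(config: FixtureConfig, rng) -> tuple[pd.DataFrame, dict]:
    """ROH segments: a planted shared region plus per-individual random
    background covering a fixed fraction of the genome."""
    ids = _sample_ids("H", config.n_roh_samples)
    p = config.planted_roh
    carriers = _exact_carriers(rng, ids, p.carrier_fraction)
    genome = config.n_chromosomes * config.chrom_length_bp
    lmin, lmax = config.background_roh_length
    mean_len = (lmin + lmax) / 2
    n_bg_per_ind = max(1, round(config.background_roh_genome_fraction
                                * genome / mean_len))
    rows = []
    totals = {sid: 0 for sid in ids}
    for sid in ids:
        if sid in carriers:
            rows.append({"sample_id": sid, "chrom": p.chrom,
                         "start": p.start, "end": p.end})
            totals[sid] += p.end - p.start + 1
        for _ in range(n_bg_per_ind):
            chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
            length = int(rng.integers(lmin, lmax + 1))
            start = int(rng.integers(1, config.chrom_length_bp - length + 1))
            rows.append({"sample_id": sid, "chrom": chrom,
                         "start": start, "end": start + length - 1})
            totals[sid] += length
    df = pd.DataFrame(rows)
    df["n_snps"] = (df["end"] - df["start"] + 1) // 5000
    df["length_kb"] = (df["end"] - df["start"] + 1) / 1000.0
    df["fid"] = df["sample_id"]
    ledger = {
        "samples": ids,
        "planted_region": {"chrom": p.chrom, "start": p.start, "end": p.end},
        "planted_carriers": carriers,
        "sum_l_roh_bp": totals,
        "autosome_lengths": config.autosome_lengths,
        "f_roh": {sid: totals[sid] / genome for sid in ids},
    }
    return df, ledger


def gen_maps(config: FixtureConfig, rng
             ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """A default-assembly SNP map and a perturbed target-assembly copy.

    Perturbation classes (disjoint marker sets): dropped from the target,
    moved to another chromosome, or position-shifted; optionally every
    surviving target position is shifted by a uniform offset.
    """
    per_chrom = config.n_snps // config.n_chromosomes
    rows = []
    for chrom in config.chromosomes:
        pos = np.sort(rng.choice(
            np.arange(1, config.chrom_length_bp + 1), size=per_chrom,
            replace=False))
        for i, pp in enumerate(pos):
            rows.append({"snp_name": f"SNP_{chrom}_{i + 1:05d}",
                         "chrom": chrom, "pos": int(pp)})
    default = pd.DataFrame(rows)

    n = len(default)
    n_missing = round(config.map_missing_rate * n)
    n_chrch = round(config.map_chr_change_rate * n)
    n_shift = round(config.map_shift_rate * n)
    perm = rng.permutation(n)
    miss_idx = perm[:n_missing]
    chrch_idx = perm[n_missing:n_missing + n_chrch]
    shift_idx = perm[n_missing + n_chrch:n_missing + n_chrch + n_shift]

    target = default.copy()
    smin, smax = config.map_shift_range
    for i in shift_idx:
        delta = int(rng.integers(smin, smax + 1)) * (1 if rng.random() < 0.5 else -1)
        target.loc[i, "pos"] = max(1, int(target.loc[i, "pos"]) + delta)
    for i in chrch_idx:
        cur = target.loc[i, "chrom"]
        others = [c for c in config.chromosomes if c != cur]
        target.loc[i, "chrom"] = others[int(rng.integers(len(others)))]
        target.loc[i, "pos"] = int(rng.integers(1, config.chrom_length_bp + 1))
    target = target.drop(index=miss_idx).reset_index(drop=True)
    if config.map_uniform_shift_bp:
        target["pos"] = target["pos"] + config.map_uniform_shift_bp
    ledger = {
        "n_snps": int(n),
        "missing_in_target": sorted(default.loc[miss_idx, "snp_name"].tolist()),
        "chr_changed": sorted(default.loc[chrch_idx, "snp_name"].tolist()),
        "position_shifted": sorted(default.loc[shift_idx, "snp_name"].tolist()),
        "uniform_shift_bp": int(config.map_uniform_shift_bp),
    }
    return default, target, ledger


def gen_refgene(config: FixtureConfig, rng) -> tuple[pd.DataFrame, dict]:
    """Random gene spans in UCSC refGene layout, a controlled fraction of
    them duplicated as extra transcript rows, plus the planted gene."""
    rows = []
    truth_names = set()
    for i in range(config.n_genes):
        chrom = config.chromosomes[int(rng.integers(config.n_chromosomes))]
        length = int(rng.integers(5_000, 500_000))
        start1 = int(rng.integers(1, config.chrom_length_bp - length))
        name = f"GENE{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        truth_names.add((name, chrom))
        # UCSC rows are 0-based half-open: txStart = start1 - 1
        rows.append((name, chrom, strand, start1 - 1, start1 - 1 + length))
        if rng.random() < config.gene_duplicate_fraction:
            shift = int(rng.integers(-2_000, 2_001))
            s2 = max(0, start1 - 1 + shift)
            rows.append((name, chrom, strand, s2, s2 + length))
    p = config.planted_cnvr
    if p.gene_name:
        gs = p.start + (p.end - p.start) // 4
        ge = p.end - (p.end - p.start) // 4
        truth_names.add((p.gene_name, p.chrom))
        rows.append((p.gene_name, p.chrom, "+", gs - 1, ge))
    flat = pd.DataFrame({
        "bin": 0,
        "name": [f"NM_{i:06d}" for i in range(len(rows))],
        "chrom": [f"chr{r[1]}" for r in rows],
        "strand": [r[2] for r in rows],
        "txStart": [r[3] for r in rows],
        "txEnd": [r[4] for r in rows],
        "cdsStart": [r[3] for r in rows],
        "cdsEnd": [r[4] for r in rows],
        "exonCount": 1,
        "exonStarts": [f"{r[3]}," for r in rows],
        "exonEnds": [f"{r[4]}," for r in rows],
        "score": 0,
        "name2": [r[0] for r in rows],
    })
    ledger = {"n_transcript_rows": len(flat),
              "n_distinct_genes": len(truth_names),
              "planted_gene": p.gene_name}
    return flat, ledger


def _hap_patterns(n_snps: int, k: int) -> list[str]:
    """k distinct 0/1 allele strings of length n_snps."""
    pats = ["0" * n_snps, "1" * n_snps,
            "".join("10"[(i % 2)] for i in range(n_snps))]
    i = 1
    while len(pats) < k:
        cand = format(i, f"0{n_snps}b")[-n_snps:]
        if cand not in pats:
            pats.append(cand)
        i += 1
    return pats[:k]


def gen_phased(config: FixtureConfig, rng) -> tuple[pd.DataFrame, dict]:
    """Phased diploid genotypes drawn from a planted haplotype
    distribution over one SNP window.

    Returns a site table plus a ledger with the exact sampled haplotype
    counts (the 2N haploid draws are individually recorded, so recovered
    frequencies are ledger equalities, not approximations).
    """
    n_snps = config.n_hap_snps
    pats = _hap_patterns(n_snps, len(config.haplotype_freqs))
    ref = rng.choice(_BASES, size=n_snps)
    alt = np.array([rng.choice([b for b in _BASES if b != r]) for r in ref])
    n_hap = 2 * config.n_hap_samples
    draws = rng.choice(len(pats), size=n_hap, p=np.array(config.haplotype_freqs))
    ids = _sample_ids("P", config.n_hap_samples)
    assignment = {}
    counts = {pat: 0 for pat in pats}
    for i, sid in enumerate(ids):
        h1, h2 = pats[draws[2 * i]], pats[draws[2 * i + 1]]
        assignment[sid] = (h1, h2)
        counts[h1] += 1
        counts[h2] += 1
    sites = pd.DataFrame({
        "snp_name": [f"HAPSNP_{i + 1:03d}" for i in range(n_snps)],
        "chrom": config.planted_roh.chrom,
        "pos": [1_000_000 + 10_000 * i for i in range(n_snps)],
        "ref": ref, "alt": alt,
    })

    def to_letters(code: str) -> str:
        return "".join(ref[j] if c == "0" else alt[j] for j, c in enumerate(code))

    ledger = {
        "patterns": pats,
        "planted_freqs": list(config.haplotype_freqs),
        "counts_codes": counts,
        "counts_letters": {to_letters(k): v for k, v in counts.items()},
        "n_individuals": config.n_hap_samples,
        "assignment": {s: list(v) for s, v in assignment.items()},
    }
    sites.attrs["assignment"] = assignment
    return sites, ledger


def write_phased_vcf(sites: pd.DataFrame, assignment: dict[str, tuple[str, str]],
                     path) -> None:
    """Write phased genotypes as an uncompressed VCF v4.2."""
    samples = list(assignment)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(sites["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, row in enumerate(sites.itertuples()):
            gts = "\t".join(
                f"{assignment[s][0][j]}|{assignment[s][1][j]}" for s in samples)
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_name}\t{row.ref}\t"
                     f"{row.alt}\t.\tPASS\t.\tGT\t{gts}\n")


def gen_cohort(config: FixtureConfig, outdir) -> dict:
    """Generate the full fixture cohort into ``outdir``.

    Writes every dialect the toolkit reads and a ``truth.json`` ledger;
    returns the ledger (which also records the file paths).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    cnv, cnv_ledger = gen_cnv(config, rng)
    roh, roh_ledger = gen_roh(config, rng)
    default_map, target_map, map_ledger = gen_maps(config, rng)
    refgene, gene_ledger = gen_refgene(config, rng)
    sites, hap_ledger = gen_phased(config, rng)

    files = {
        "penncnv": str(outdir / "cnv.penncnv.txt"),
        "cnvpartition": str(outdir / "cnv.cnvpartition.csv"),
        "hom": str(outdir / "plink.hom"),
        "map_default": str(outdir / "default.map"),
        "map_target": str(outdir / "target.map"),
        "refgene": str(outdir / "refgene.txt"),
        "vcf": str(outdir / "phased.vcf"),
        "ledger": str(outdir / "truth.json"),
    }
    write_penncnv(cnv, files["penncnv"])
    write_cnvpartition(cnv, files["cnvpartition"])
    formats_io.write_plink_hom(roh, files["hom"])
    formats_io.write_snp_map(default_map, files["map_default"])
    formats_io.write_snp_map(target_map, files["map_target"])
    refgene.to_csv(files["refgene"], sep="\t", header=False, index=False)
    write_phased_vcf(sites, sites.attrs["assignment"], files["vcf"])

    ledger = {
        "config": asdict(config),
        "files": files,
        "cnv": cnv_ledger,
        "roh": roh_ledger,
        "maps": map_ledger,
        "genes": gene_ledger,
        "haplotypes": hap_ledger,
    }
    with open(files["ledger"], "w") as fh:
        json.dump(ledger, fh, indent=1, sort_keys=True)
    return ledger
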