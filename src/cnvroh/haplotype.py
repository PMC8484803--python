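"""Locate regions on a SNP map and tabulate haplotype / diplotype
frequencies from phased genotypes.

A haplotype here is the ordered allele string on one chromosome copy over
a SNP window; a diplotype is the unordered pair of haplotypes an
individual carries (phasing is arbitrary with respect to parent of
origin, so (H1,H2) and (H2,H1) are the same diplotype). Haplotype
frequency is count / 2N over the 2N haploid sequences; diplotype
frequency is count / N over the N individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from cnvroh.formats_io import PhasedGenotypes


@dataclass
class SnpWindow:
    """An ordered run of map SNPs covering a query region."""

    chrom: str
    snp_names: list[str]
    index_first: int
    index_last: int
    pos_first_bp: int
    pos_last_bp: int
    flanking_only: bool = False

    @property
    def n_snps(self) -> int:
        return len(self.snp_names)


def closer_snp(map_df: pd.DataFrame, chrom, start_bp: int, end_bp: int) -> SnpWindow:
    """SNPs of the map falling inside [start_bp, end_bp] on ``chrom``.

    If no marker lies inside the region, the window falls back to the two
    flanking markers (nearest below the start and nearest above the end)
    and is flagged ``flanking_only``. The map must be sorted by
    (chrom, pos); indices refer to per-chromosome map order.
    """
    chrom = str(chrom)
    sub = map_df[map_df["chrom"].astype(str) == chrom]
    if len(sub) == 0:
        raise ValueError(f"chromosome {chrom!r} not present in the SNP map")
    sub = sub.sort_values("pos", kind="mergesort").reset_index(drop=True)
    inside = sub[(sub["pos"] >= start_bp) & (sub["pos"] <= end_bp)]
    if len(inside):
        i0, i1 = int(inside.index[0]), int(inside.index[-1])
        return SnpWindow(
            chrom=chrom, snp_names=inside["snp_name"].tolist(),
            index_first=i0, index_last=i1,
            pos_first_bp=int(inside["pos"].iloc[0]),
            pos_last_bp=int(inside["pos"].iloc[-1]))
    below = sub[sub["pos"] < start_bp]
    above = sub[sub["pos"] > end_bp]
    if len(below) == 0 and len(above) == 0:   # empty chromosome handled above
        raise ValueError(f"no markers on chromosome {chrom!r}")
    picks = []
    if len(below):
        picks.append(below.index[-1])
    if len(above):
        picks.append(above.index[0])
    flank = sub.loc[picks]
    return SnpWindow(
        chrom=chrom, snp_names=flank["snp_name"].tolist(),
        index_first=int(picks[0]), index_last=int(picks[-1]),
        pos_first_bp=int(flank["pos"].iloc[0]),
        pos_last_bp=int(flank["pos"].iloc[-1]),
        flanking_only=True)


def get_haplotype(geno: PhasedGenotypes, window: SnpWindow | list[str]
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Haplotype and diplotype frequency tables over a SNP window.

    Returns ``(haplotypes, diplotypes)``:

    * ``haplotypes``: one row per distinct allele string among the 2N
      haploid sequences, with ``haplotype_id`` (H1, H2, ... by descending
      count, ties broken lexicographically by allele string), ``count``
      and ``freq = count / 2N``.
    * ``diplotypes``: one row per unordered haplotype pair among the N
      individuals, with ``count`` and ``freq = count / N``.

    Frequencies in each table sum to exactly 1 (integer count
    arithmetic). A window SNP absent from the genotypes raises KeyError.
    """
    names = window.snp_names if isinstance(window, SnpWindow) else list(window)
    sliced = geno.subset(names)
    n = sliced.n_samples
    if n == 0:
        raise ValueError("no individuals in the phased genotypes")

    hap_counts: dict[str, int] = {}
    dip_counts: dict[tuple[str, str], int] = {}
    per_sample: dict[str, tuple[str, str]] = {}
    for s, (h1, h2) in sliced.haplotypes.items():
        a, b = "".join(h1), "".join(h2)
        hap_counts[a] = hap_counts.get(a, 0) + 1
        hap_counts[b] = hap_counts.get(b, 0) + 1
        pair = tuple(sorted((a, b)))
        dip_counts[pair] = dip_counts.get(pair, 0) + 1
        per_sample[s] = pair

    ordered = sorted(hap_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    hap_id = {h: f"H{i + 1}" for i, (h, _) in enumerate(ordered)}
    haplotypes = pd.DataFrame({
        "haplotype_id": [hap_id[h] for h, _ in ordered],
        "haplotype": [h for h, _ in ordered],
        "count": [c for _, c in ordered],
        "freq": [c / (2 * n) for _, c in ordered],
    })

    dip_ordered = sorted(dip_counts.items(),
                         key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    diplotypes = pd.DataFrame({
        "diplotype": [f"{hap_id[a]}/{hap_id[b]}" for (a, b), _ in dip_ordered],
        "haplotype_1": [a for (a, _b), _ in dip_ordered],
        "haplotype_2": [b for (_a, b), _ in dip_ordered],
        "count": [c for _, c in dip_ordered],
        "freq": [c / n for _, c in dip_ordered],
    })
    diplotypes.attrs["per_sample"] = per_sample
    return haplotypes, diplotypes
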