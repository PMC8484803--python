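"""Readers and writers for every external file dialect the toolkit touches.

Input dialects
--------------
* CNV calls: PennCNV raw text output, CNVPartition CSV export, and the
  toolkit's own tab-delimited standard table.
* ROH segments: PLINK ``.hom`` tables.
* SNP maps: PLINK ``.map`` and ``.bim``.
* Gene models: UCSC refGene / ensGene flat tables.
* Phased genotypes: VCF with phased GT fields (Beagle-style ``0|1``).

All coordinates in the internal model are 1-based fully-closed intervals.
The refGene reader is the single place a base shift occurs: UCSC txStart is
0-based half-open and is shifted by +1 on the way in. Chromosome labels are
kept verbatim on the raw record and normalized (``chr`` prefix stripped)
downstream by :func:`cnvroh.cnv.clean_cnv` and friends.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from cnvroh._util import normalize_chrom

logger = logging.getLogger(__name__)

CNV_DIALECTS = ("penncnv", "cnvpartition", "generic")

#: Fixed header of the internal standard CNV table dialect.
STANDARD_CNV_COLUMNS = ["sample_id", "chr", "start", "end", "cn", "n_snps", "length"]

#: Default column map for the CNVPartition CSV export.
CNVPARTITION_COLUMNS = {
    "sample_id": "SampleID",
    "chrom": "Chr",
    "start": "StartPosition",
    "end": "EndPosition",
    "cn": "CopyNumber",
    "confidence": "Confidence",
}


class DialectError(ValueError):
    """The file does not look like the requested dialect."""


class SchemaError(ValueError):
    """A required column is missing from a tabular input."""


@dataclass
class RawCnvRecord:
    """One CNV call as read from a detection tool, before standardization."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    copy_number: int
    num_snps: int | None = None
    confidence: float | None = None
    source_dialect: str = "generic"
    source_path: str | None = None
    line_number: int | None = None

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError(
                f"end_bp {self.end_bp} < start_bp {self.start_bp} "
                f"({self.source_path}:{self.line_number})"
            )
        if self.copy_number < 0:
            raise ValueError(f"negative copy number {self.copy_number}")


@dataclass
class MalformedLine:
    line_number: int
    text: str
    reason: str


@dataclass
class ParsedCnv:
    """CNV records plus the malformed lines that were set aside."""

    records: list[RawCnvRecord]
    malformed: list[MalformedLine] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


# PennCNV raw line, e.g.
#   chr1:100-299   numsnp=10  length=200  state2,cn=1 SAMPLE startsnp=rs1 endsnp=rs9 conf=15.5
_PENNCNV_LOCUS = re.compile(r"^(?:chr)?(\w+):([\d,]+)-([\d,]+)$")


def _parse_penncnv_line(line: str):
    tokens = line.split()
    if len(tokens) < 5:
        raise ValueError("fewer than 5 whitespace-separated tokens")
    m = _PENNCNV_LOCUS.match(tokens[0])
    if m is None:
        raise ValueError(f"first token {tokens[0]!r} is not a chr:start-end locus")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    fields = {}
    sample = None
    for tok in tokens[1:]:
        if "=" in tok:
            key, _, val = tok.partition("=")
            if key == "state" or "," in key:
                # "state2,cn" arrives as key "state2,cn"
                key = key.split(",")[-1]
            fields[key] = val
        elif sample is None:
            sample = tok
    if "cn" not in fields:
        raise ValueError("no cn= token")
    if sample is None:
        raise ValueError("no sample token")
    # PennCNV emits the genotype-file path as sample; keep the basename stem.
    sample_id = Path(sample).name
    num_snps = int(fields["numsnp"].replace(",", "")) if "numsnp" in fields else None
    conf = float(fields["conf"]) if "conf" in fields else None
    return sample_id, chrom, start, end, int(fields["cn"]), num_snps, conf


def read_cnv(path, dialect: str = "penncnv",
             column_map: dict[str, str] | None = None) -> ParsedCnv:
    """Parse a CNV call file into raw records.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"penncnv"`` (raw whitespace output), ``"cnvpartition"``
        (comma-separated export) or ``"generic"`` (the internal
        tab-delimited standard table).
    column_map
        For the cnvpartition/generic dialects, optional mapping from the
        internal field names (``sample_id``, ``chrom``, ``start``, ``end``,
        ``cn``, and optionally ``n_snps``/``confidence``) to the column
        names present in the file.

    Malformed lines are collected on the result, not silently dropped; if
    more than half of the non-empty lines are malformed a
    :class:`DialectError` naming the first offender is raised.
    """
    path = Path(path)
    if dialect not in CNV_DIALECTS:
        raise ValueError(f"unknown CNV dialect {dialect!r}; expected one of {CNV_DIALECTS}")
    if dialect == "penncnv":
        return _read_penncnv(path)
    return _read_cnv_table(path, dialect, column_map)


def _read_penncnv(path: Path) -> ParsedCnv:
    records: list[RawCnvRecord] = []
    malformed: list[MalformedLine] = []
    n_nonempty = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_nonempty += 1
            try:
                sample, chrom, start, end, cn, nsnp, conf = _parse_penncnv_line(line)
                records.append(RawCnvRecord(
                    sample_id=sample, chrom=chrom, start_bp=start, end_bp=end,
                    copy_number=cn, num_snps=nsnp, confidence=conf,
                    source_dialect="penncnv", source_path=str(path),
                    line_number=lineno,
                ))
            except (ValueError, IndexError) as exc:
                malformed.append(MalformedLine(lineno, line, str(exc)))
    if n_nonempty == 0:
        logger.warning("empty CNV file: %s", path)
    elif len(malformed) * 2 > n_nonempty:
        first = malformed[0]
        raise DialectError(
            f"{path}: {len(malformed)}/{n_nonempty} lines malformed for dialect "
            f"'penncnv'; first offending line {first.line_number}: {first.text!r} "
            f"({first.reason})"
        )
    return ParsedCnv(records, malformed)


def _read_cnv_table(path: Path, dialect: str,
                    column_map: dict[str, str] | None) -> ParsedCnv:
    if dialect == "cnvpartition":
        cmap = dict(CNVPARTITION_COLUMNS)
        sep = ","
    else:
        cmap = {"sample_id": "sample_id", "chrom": "chr", "start": "start",
                "end": "end", "cn": "cn", "n_snps": "n_snps"}
        sep = "\t"
    if column_map:
        cmap.update(column_map)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        logger.warning("empty CNV file: %s", path)
        return ParsedCnv([])
    required = ["sample_id", "chrom", "start", "end", "cn"]
    missing = [cmap[k] for k in required if cmap[k] not in df.columns]
    if missing:
        raise DialectError(
            f"{path}: columns {missing} not found for dialect {dialect!r} "
            f"(present: {list(df.columns)})"
        )
    records: list[RawCnvRecord] = []
    malformed: list[MalformedLine] = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        lineno = i + 2  # header is line 1
        try:
            records.append(RawCnvRecord(
                sample_id=str(rowd[cmap["sample_id"]]),
                chrom=str(rowd[cmap["chrom"]]),
                start_bp=int(rowd[cmap["start"]]),
                end_bp=int(rowd[cmap["end"]]),
                copy_number=int(rowd[cmap["cn"]]),
                num_snps=(int(rowd[cmap["n_snps"]])
                          if "n_snps" in cmap and cmap["n_snps"] in df.columns
                          and pd.notna(rowd[cmap["n_snps"]]) else None),
                confidence=(float(rowd[cmap["confidence"]])
                            if "confidence" in cmap and cmap.get("confidence") in df.columns
                            and pd.notna(rowd[cmap["confidence"]]) else None),
                source_dialect=dialect, source_path=str(path), line_number=lineno,
            ))
        except (ValueError, TypeError) as exc:
            malformed.append(MalformedLine(lineno, str(rowd), str(exc)))
    if malformed and len(malformed) * 2 > len(df):
        first = malformed[0]
        raise DialectError(
            f"{path}: {len(malformed)}/{len(df)} rows malformed for dialect "
            f"{dialect!r}; first offending line {first.line_number}: {first.reason}"
        )
    return ParsedCnv(records, malformed)


def write_standard_cnv(cnv: pd.DataFrame, path) -> None:
    """Write a standardized CNV table in the internal tab-delimited dialect."""
    out = cnv.rename(columns={"chrom": "chr"})
    cols = [c for c in STANDARD_CNV_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


HOM_REQUIRED = ["FID", "IID", "CHR", "POS1", "POS2", "KB", "NSNP"]


def read_plink_hom(path) -> pd.DataFrame:
    """Read a PLINK ``.hom`` ROH table.

    Returns a frame with columns ``sample_id, chrom, start, end, n_snps,
    length_kb, length_bp, fid`` — one row per homozygous segment. The
    sample identifier is IID; FID is preserved in the ``fid`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+")
    missing = [c for c in HOM_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: .hom file missing required columns {missing}")
    out = pd.DataFrame({
        "sample_id": df["IID"].astype(str),
        "chrom": df["CHR"].map(normalize_chrom),
        "start": df["POS1"].astype(int),
        "end": df["POS2"].astype(int),
        "n_snps": df["NSNP"].astype(int),
        "length_kb": df["KB"].astype(float),
        "fid": df["FID"].astype(str),
    })
    out["length_bp"] = out["end"] - out["start"] + 1
    out.attrs["source_path"] = str(path)
    return out


def write_plink_hom(roh: pd.DataFrame, path) -> None:
    """Write a ROH table in PLINK ``.hom`` layout (whitespace-delimited)."""
    out = pd.DataFrame({
        "FID": roh["fid"] if "fid" in roh.columns else roh["sample_id"],
        "IID": roh["sample_id"],
        "CHR": roh["chrom"],
        "POS1": roh["start"],
        "POS2": roh["end"],
        "KB": roh["length_kb"] if "length_kb" in roh.columns
              else (roh["end"] - roh["start"] + 1) / 1000.0,
        "NSNP": roh["n_snps"],
    })
    out.to_csv(path, sep=" ", index=False)


@dataclass
class DuplicateSnpReport:
    snp_name: str
    count: int


def read_snp_map(path, dialect: str = "map"):
    """Read a PLINK ``.map`` or ``.bim`` SNP map.

    Returns ``(map_df, duplicates)`` where ``map_df`` has columns
    ``snp_name, chrom, pos`` in file order and ``duplicates`` lists SNP
    names that occurred more than once (first occurrence kept).
    """
    path = Path(path)
    if dialect not in ("map", "bim"):
        raise ValueError(f"unknown SNP map dialect {dialect!r}")
    names = (["chrom", "snp_name", "cm", "pos"] if dialect == "map"
             else ["chrom", "snp_name", "cm", "pos", "a1", "a2"])
    df = pd.read_csv(path, sep=r"\s+", header=None, names=names, dtype=str)
    try:
        pos = df["pos"].astype(int)
    except ValueError as exc:
        bad = df.index[pd.to_numeric(df["pos"], errors="coerce").isna()][0]
        raise ValueError(f"{path}: non-integer position on line {bad + 1}") from exc
    out = pd.DataFrame({
        "snp_name": df["snp_name"].astype(str),
        "chrom": df["chrom"].map(normalize_chrom),
        "pos": pos,
    })
    dup_mask = out["snp_name"].duplicated(keep="first")
    duplicates = [
        DuplicateSnpReport(name, int(n))
        for name, n in out.loc[out["snp_name"].duplicated(keep=False), "snp_name"]
        .value_counts().items()
    ] if dup_mask.any() else []
    out = out[~dup_mask].reset_index(drop=True)
    out.attrs["source_path"] = str(path)
    return out, duplicates


def write_snp_map(map_df: pd.DataFrame, path) -> None:
    """Write a SNP map in PLINK ``.map`` layout (chrom, name, 0, pos)."""
    out = pd.DataFrame({
        "chrom": map_df["chrom"], "snp_name": map_df["snp_name"],
        "cm": 0, "pos": map_df["pos"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


# UCSC refGene flat layout; name2 (gene symbol) is column 12.
_REFGENE_COLS = ["bin", "name", "chrom", "strand", "txStart", "txEnd",
                 "cdsStart", "cdsEnd", "exonCount", "exonStarts", "exonEnds",
                 "score", "name2"]


def read_refgene(path, source: str = "ucsc_refgene") -> pd.DataFrame:
    """Read a UCSC refGene/ensGene flat table into a cleaned gene list.

    Transcript rows are collapsed per (gene, chromosome) to the union span
    [min txStart, max txEnd]; txStart is shifted from UCSC 0-based
    half-open to 1-based inclusive. Returns columns
    ``gene_name, chrom, start, end, strand``.
    """
    if source not in ("ucsc_refgene", "ensgene"):
        raise ValueError(f"unknown gene-list source {source!r}")
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if raw.shape[1] < 13:
        raise SchemaError(
            f"{path}: expected >=13 refGene columns, found {raw.shape[1]}"
        )
    raw = raw.iloc[:, :13]
    raw.columns = _REFGENE_COLS
    df = pd.DataFrame({
        "gene_name": raw["name2"].astype(str),
        "chrom": raw["chrom"].map(normalize_chrom),
        "start": raw["txStart"].astype(int) + 1,
        "end": raw["txEnd"].astype(int),
        "strand": raw["strand"].where(raw["strand"].isin(["+", "-"]), "unknown"),
    })
    grouped = df.groupby(["gene_name", "chrom"], sort=False).agg(
        start=("start", "min"), end=("end", "max"), strand=("strand", "first"),
    ).reset_index()
    grouped.attrs["source_path"] = str(path)
    return grouped


class PhasedGenotypes:
    """Phased genotypes over an ordered SNP set.

    Attributes
    ----------
    sites : pandas.DataFrame
        Columns ``snp_name, chrom, pos, ref, alt`` in file order.
    samples : list of str
    haplotypes : dict
        sample_id -> (hap1, hap2), each a list of single-character alleles
        (REF/ALT letters, or '0'/'1' codes when ``convert_letter=False``).
    """

    def __init__(self, sites: pd.DataFrame, haplotypes: dict[str, tuple[list, list]]):
        self.sites = sites.reset_index(drop=True)
        self.haplotypes = haplotypes
        self.samples = list(haplotypes)
        n = len(self.sites)
        for s, (h1, h2) in haplotypes.items():
            if len(h1) != n or len(h2) != n:
                raise ValueError(f"haplotype length mismatch for sample {s}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, snp_names: Sequence[str]) -> "PhasedGenotypes":
        """Restrict to the given SNPs (kept in their current order)."""
        name_to_idx = {n: i for i, n in enumerate(self.sites["snp_name"])}
        missing = [n for n in snp_names if n not in name_to_idx]
        if missing:
            raise KeyError(f"SNPs not present in phased genotypes: {missing}")
        idx = [name_to_idx[n] for n in snp_names]
        sites = self.sites.iloc[idx]
        haps = {s: ([h1[i] for i in idx], [h2[i] for i in idx])
                for s, (h1, h2) in self.haplotypes.items()}
        return PhasedGenotypes(sites, haps)


def read_phased_vcf(path, convert_letter: bool = True) -> PhasedGenotypes:
    """Read phased genotypes (Beagle-style ``0|1`` GT) from a VCF.

    With ``convert_letter=True`` allele codes are mapped to REF/ALT bases;
    otherwise the '0'/'1' codes are kept. Unphased or multi-allelic sites
    raise a ``ValueError`` naming the first offending site.
    """
    path = str(path)
    vcf = pysam.VariantFile(path)
    samples = list(vcf.header.samples)
    sites_rows = []
    haps: dict[str, tuple[list, list]] = {s: ([], []) for s in samples}
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            raise ValueError(
                f"{path}: site {rec.chrom}:{rec.pos} is not bi-allelic "
                f"(ALT={rec.alts}); multi-allelic sites are not supported"
            )
        ref, alt = rec.ref, rec.alts[0]
        for s in samples:
            gt = rec.samples[s]
            alleles = gt["GT"]
            if alleles is None or len(alleles) != 2 or not gt.phased:
                raise ValueError(
                    f"{path}: unphased or missing genotype for sample {s} "
                    f"at {rec.chrom}:{rec.pos}"
                )
            if convert_letter:
                codes = (ref if alleles[0] == 0 else alt,
                         ref if alleles[1] == 0 else alt)
            else:
                codes = (str(alleles[0]), str(alleles[1]))
            haps[s][0].append(codes[0])
            haps[s][1].append(codes[1])
        sites_rows.append({
            "snp_name": rec.id if rec.id else f"{rec.chrom}:{rec.pos}",
            "chrom": normalize_chrom(rec.chrom), "pos": rec.pos,
            "ref": ref, "alt": alt,
        })
    vcf.close()
    sites = pd.DataFrame(sites_rows, columns=["snp_name", "chrom", "pos", "ref", "alt"])
    return PhasedGenotypes(sites, haps)


# prep_phased is the field name for loading + letter-converting phased VCFs.
prep_phased = read_phased_vcf


def write_table(df: pd.DataFrame, path) -> None:
    """Write any internal table as tab-delimited with header."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
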