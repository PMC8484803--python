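"""End-to-end pipelines composing the library operations.

Each run writes its artifacts into a dedicated output directory and
returns a manifest listing every file produced with its SHA-256 checksum,
so reruns can be verified byte-for-byte and different runs never collide.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from cnvroh import annotation, cnv as cnv_mod, cnvr as cnvr_mod, formats_io
from cnvroh import haplotype as hap_mod
from cnvroh import mapconv, roh as roh_mod

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; prior outputs are preserved."""


@dataclass
class RunConfig:
    outdir: str
    overwrite: bool = False

    # CNV pipeline inputs
    cnv_path: str | None = None
    cnv_dialect: str = "penncnv"
    refgene_path: str | None = None
    sample_size: int | None = None
    common_cnv_threshold: float = cnvr_mod.DEFAULT_COMMON_CNV_THRESHOLD
    length_breaks: tuple = cnv_mod.DEFAULT_LENGTH_BREAKS

    # ROH pipeline inputs
    hom_path: str | None = None
    map_path: str | None = None
    roh_freq_threshold: float = roh_mod.DEFAULT_ROH_FREQ_THRESHOLD
    roh_length_breaks: tuple = roh_mod.DEFAULT_ROH_LENGTH_BREAKS
    autosome_lengths: dict | None = None

    # optional haplotype step
    phased_vcf_path: str | None = None
    haplotype_region: tuple | None = None   # (chrom, start_bp, end_bp)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.entries: list[dict] = []

    def add(self, name: str, path: Path):
        self.entries.append({"name": name, "file": str(path),
                             "sha256": _sha256(path)})

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=1)
        return path


def _prepare_outdir(config: RunConfig) -> Path:
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.overwrite:
        raise PipelineError(
            f"output directory {outdir} is not empty; choose a fresh "
            f"directory or pass overwrite=True")
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_cnv_pipeline(config: RunConfig) -> list[dict]:
    """clean -> summarize -> call_cnvr -> annotate -> gene frequency ->
    high-frequency CNVRs. Returns the artifact manifest."""
    if config.cnv_path is None:
        raise PipelineError("cnv_path is required for the CNV pipeline")
    outdir = _prepare_outdir(config)
    manifest = _Manifest(outdir)

    parsed = _stage("read_cnv")(formats_io.read_cnv)(
        config.cnv_path, config.cnv_dialect)
    clean, report = _stage("clean_cnv")(cnv_mod.clean_cnv)(parsed.records)
    p = outdir / "clean_cnv.tsv"
    formats_io.write_standard_cnv(clean, p)
    manifest.add("clean_cnv", p)

    summary = _stage("summarize_cnv")(cnv_mod.summarize_cnv)(
        clean, config.length_breaks)
    p = outdir / "cnv_summary.tsv"
    formats_io.write_table(summary.brief_table(), p)
    manifest.add("cnv_summary", p)

    cnvr, membership = _stage("call_cnvr")(cnvr_mod.call_cnvr)(clean)
    p = outdir / "cnvr.tsv"
    formats_io.write_table(cnvr, p)
    manifest.add("cnvr", p)
    brief, per_chrom = cnvr_mod.cnvr_summaries(cnvr, config.length_breaks)
    p = outdir / "cnvr_summary.tsv"
    formats_io.write_table(brief, p)
    manifest.add("cnvr_summary", p)
    p = outdir / "cnvr_per_chromosome.tsv"
    formats_io.write_table(per_chrom, p)
    manifest.add("cnvr_per_chromosome", p)

    sample_size = config.sample_size or clean["sample_id"].nunique()
    high = _stage("high_freq_cnvr")(cnvr_mod.high_freq_cnvr)(
        cnvr, sample_size, config.common_cnv_threshold)
    p = outdir / "high_freq_cnvr.tsv"
    formats_io.write_table(high, p)
    manifest.add("high_freq_cnvr", p)

    if config.refgene_path:
        genes = _stage("read_refgene")(formats_io.read_refgene)(config.refgene_path)
        annotated = _stage("annotate")(annotation.annotate_intervals)(clean, genes)
        p = outdir / "cnv_gene_annotation.tsv"
        formats_io.write_table(annotated, p)
        manifest.add("cnv_gene_annotation", p)
        freq = _stage("gene_frequency")(annotation.gene_frequency)(
            annotated, sample_size)
        p = outdir / "gene_frequency.tsv"
        formats_io.write_table(freq, p)
        manifest.add("gene_frequency", p)

    manifest.write()
    logger.info("CNV pipeline complete: %d artifacts in %s",
                len(manifest.entries), outdir)
    return manifest.entries


def run_roh_pipeline(config: RunConfig) -> list[dict]:
    """density -> length summary -> F_roh -> incidence -> high-frequency
    regions -> annotate -> optional haplotypes. Returns the manifest."""
    if config.hom_path is None or config.map_path is None:
        raise PipelineError(".hom and .map paths are required for the ROH pipeline")
    outdir = _prepare_outdir(config)
    manifest = _Manifest(outdir)

    roh = _stage("read_plink_hom")(formats_io.read_plink_hom)(config.hom_path)
    map_df, _dups = _stage("read_snp_map")(formats_io.read_snp_map)(config.map_path)

    density = _stage("snp_density")(mapconv.snp_density)(map_df)
    p = outdir / "snp_density.tsv"
    formats_io.write_table(density, p)
    manifest.add("snp_density", p)

    lsum = _stage("roh_length_summary")(roh_mod.roh_length_summary)(
        roh, config.roh_length_breaks)
    p = outdir / "roh_length_summary.tsv"
    formats_io.write_table(lsum, p)
    manifest.add("roh_length_summary", p)

    auto = config.autosome_lengths or roh_mod.autosome_lengths_from_map(map_df)
    inb = _stage("froh")(roh_mod.froh)(roh, auto, config.roh_length_breaks)
    p = outdir / "inbreeding.tsv"
    formats_io.write_table(inb, p)
    manifest.add("inbreeding", p)

    incidence = _stage("roh_incidence")(roh_mod.roh_incidence)(roh, map_df)
    p = outdir / "roh_incidence.tsv"
    formats_io.write_table(incidence, p)
    manifest.add("roh_incidence", p)

    high = _stage("high_freq_roh")(roh_mod.high_freq_roh)(
        incidence, config.roh_freq_threshold)
    p = outdir / "high_freq_roh.tsv"
    formats_io.write_table(high, p)
    manifest.add("high_freq_roh", p)

    if config.refgene_path and len(high):
        genes = _stage("read_refgene")(formats_io.read_refgene)(config.refgene_path)
        annot = _stage("annotate")(annotation.call_gene)(
            high.reset_index().rename(columns={"index": "interval_id"}), genes)
        p = outdir / "roh_gene_annotation.tsv"
        formats_io.write_table(annot, p)
        manifest.add("roh_gene_annotation", p)

    if config.phased_vcf_path and config.haplotype_region:
        geno = _stage("read_phased_vcf")(formats_io.read_phased_vcf)(
            config.phased_vcf_path, convert_letter=True)
        chrom, start, end = config.haplotype_region
        window = _stage("closer_snp")(hap_mod.closer_snp)(
            geno.sites, chrom, start, end)
        haps, dips = _stage("get_haplotype")(hap_mod.get_haplotype)(geno, window)
        p = outdir / "haplotype_freq.tsv"
        formats_io.write_table(haps, p)
        manifest.add("haplotype_freq", p)
        p = outdir / "diplotype_freq.tsv"
        formats_io.write_table(dips, p)
        manifest.add("diplotype_freq", p)

    manifest.write()
    logger.info("ROH pipeline complete: %d artifacts in %s",
                len(manifest.entries), outdir)
    return manifest.entries
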