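"""Parsing and round-trip behaviour of every input dialect."""

import pandas as pd
import pytest

from cnvroh import formats_io
from cnvroh.formats_io import (
    DialectError,
    SchemaError,
    read_cnv,
    read_phased_vcf,
    read_plink_hom,
    read_refgene,
    read_snp_map,
    write_snp_map,
    write_standard_cnv,
)


class TestPennCnv:
    def test_single_line_field_extraction(self, tmp_path):
        p = tmp_path / "calls.txt"
        p.write_text("chr1:100-299 numsnp=10 length=200 state2,cn=1 S1\n")
        parsed = read_cnv(p, "penncnv")
        (rec,) = parsed.records
        assert (rec.sample_id, rec.chrom, rec.start_bp, rec.end_bp) == ("S1", "1", 100, 299)
        assert rec.copy_number == 1 and rec.num_snps == 10
        assert rec.line_number == 1 and rec.source_path == str(p)

    def test_sample_path_reduced_to_basename(self, tmp_path):
        p = tmp_path / "calls.txt"
        p.write_text("chr2:5000-9000 numsnp=25 length=4,001 state5,cn=3 "
                     "/data/geno/S77.txt conf=21.5\n")
        rec = read_cnv(p, "penncnv").records[0]
        assert rec.sample_id == "S77.txt"
        assert rec.copy_number == 3 and rec.confidence == 21.5

    def test_empty_file_gives_empty_sequence(self, tmp_path):
        p = tmp_path / "empty.txt"
        p.write_text("")
        assert len(read_cnv(p, "penncnv")) == 0

    def test_malformed_lines_collected_with_numbers(self, tmp_path):
        p = tmp_path / "calls.txt"
        p.write_text("chr1:100-299 numsnp=10 length=200 state2,cn=1 S1\n"
                     "not a cnv line at all whatsoever here\n"
                     "chr1:400-500 numsnp=5 length=101 state2,cn=1 S2\n")
        parsed = read_cnv(p, "penncnv")
        assert len(parsed.records) == 2
        assert [m.line_number for m in parsed.malformed] == [2]

    def test_majority_malformed_raises_dialect_error(self, tmp_path):
        p = tmp_path / "calls.csv"
        p.write_text("garbage one\ngarbage two\n"
                     "chr1:100-299 numsnp=10 length=200 state2,cn=1 S1\n")
        with pytest.raises(DialectError, match="line 1"):
            read_cnv(p, "penncnv")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="dialect"):
            read_cnv(tmp_path / "x", "quantisnp")


class TestCnvTableDialects:
    def test_cnvpartition_default_columns(self, tmp_path):
        p = tmp_path / "part.csv"
        p.write_text("SampleID,Chr,StartPosition,EndPosition,CopyNumber,Confidence\n"
                     "S9,3,1000,2000,0,40.5\n")
        rec = read_cnv(p, "cnvpartition").records[0]
        assert (rec.sample_id, rec.chrom, rec.start_bp, rec.end_bp,
                rec.copy_number, rec.confidence) == ("S9", "3", 1000, 2000, 0, 40.5)

    def test_cnvpartition_custom_column_map(self, tmp_path):
        p = tmp_path / "part.csv"
        p.write_text("ID,Chromosome,From,To,CN\nS1,1,10,20,4\n")
        parsed = read_cnv(p, "cnvpartition", column_map={
            "sample_id": "ID", "chrom": "Chromosome", "start": "From",
            "end": "To", "cn": "CN"})
        assert parsed.records[0].copy_number == 4

    def test_standard_table_round_trip(self, tmp_path, clean_cohort_cnv):
        clean, _ = clean_cohort_cnv
        p = tmp_path / "std.tsv"
        write_standard_cnv(clean, p)
        back = read_cnv(p, "generic")
        assert len(back) == len(clean)
        assert back.malformed == []
        got = pd.DataFrame({
            "sample_id": [r.sample_id for r in back],
            "chrom": [r.chrom for r in back],
            "start": [r.start_bp for r in back],
            "end": [r.end_bp for r in back],
            "cn": [r.copy_number for r in back],
        })
        pd.testing.assert_frame_equal(
            got, clean[["sample_id", "chrom", "start", "end", "cn"]],
            check_dtype=False)


class TestPlinkHom:
    def test_header_only_gives_empty(self, tmp_path):
        p = tmp_path / "plink.hom"
        p.write_text("FID IID CHR POS1 POS2 KB NSNP\n")
        assert len(read_plink_hom(p)) == 0

    def test_column_mapping(self, tmp_path):
        p = tmp_path / "plink.hom"
        p.write_text("FID IID CHR POS1 POS2 KB NSNP\n"
                     "1 H007 22 22810000 23220000 410.001 120\n")
        row = read_plink_hom(p).iloc[0]
        assert row["sample_id"] == "H007" and row["chrom"] == "22"
        assert (row["start"], row["end"], row["n_snps"]) == (22810000, 23220000, 120)
        assert row["length_kb"] == pytest.approx(410.001)
        assert row["fid"] == "1"

    def test_missing_column_names_reported(self, tmp_path):
        p = tmp_path / "plink.hom"
        p.write_text("FID IID CHR POS1 POS2\n1 a 1 2 3\n")
        with pytest.raises(SchemaError, match="KB"):
            read_plink_hom(p)

    def test_fixture_segment_count_matches_generator(self, cohort, cohort_roh):
        cfg = cohort["config"]
        expected_planted = len(cohort["roh"]["planted_carriers"])
        n_bg = len(cohort_roh) - expected_planted
        assert n_bg % cfg["n_roh_samples"] == 0  # same background count per sample
        assert set(cohort_roh["sample_id"]) == set(cohort["roh"]["samples"])


class TestSnpMap:
    def test_map_row(self, tmp_path):
        p = tmp_path / "a.map"
        p.write_text("14\trs123\t0\t105000000\n")
        m, dups = read_snp_map(p, "map")
        assert m.iloc[0].tolist() == ["rs123", "14", 105000000]
        assert dups == []

    def test_bim_row(self, tmp_path):
        p = tmp_path / "a.bim"
        p.write_text("1\trs9\t0\t5000\tA\tG\n")
        m, _ = read_snp_map(p, "bim")
        assert m.iloc[0]["pos"] == 5000

    def test_duplicate_names_kept_first_and_reported(self, tmp_path):
        p = tmp_path / "a.map"
        p.write_text("1\trs9\t0\t100\n1\trs9\t0\t200\n2\trs10\t0\t300\n")
        m, dups = read_snp_map(p, "map")
        assert len(m) == 2 and m.iloc[0]["pos"] == 100
        assert [(d.snp_name, d.count) for d in dups] == [("rs9", 2)]

    def test_non_integer_position_names_line(self, tmp_path):
        p = tmp_path / "a.map"
        p.write_text("1\trs1\t0\t100\n1\trs2\t0\tabc\n")
        with pytest.raises(ValueError, match="line 2"):
            read_snp_map(p, "map")

    def test_round_trip(self, tmp_path, cohort_map):
        p = tmp_path / "rt.map"
        write_snp_map(cohort_map, p)
        back, dups = read_snp_map(p, "map")
        assert dups == []
        pd.testing.assert_frame_equal(back, cohort_map, check_dtype=False)


class TestRefGene:
    def _flat(self, rows):
        cols = []
        for name, chrom, strand, s, e, sym in rows:
            cols.append("\t".join(map(str, [
                0, name, chrom, strand, s, e, s, e, 1, f"{s},", f"{e},", 0, sym])))
        return "\n".join(cols) + "\n"

    def test_union_span_dedup_and_base_shift(self, tmp_path):
        p = tmp_path / "refgene.txt"
        p.write_text(self._flat([
            ("NM_1", "chr2", "+", 100, 500, "GENE1"),
            ("NM_2", "chr2", "+", 300, 900, "GENE1")]))
        g = read_refgene(p)
        assert len(g) == 1
        row = g.iloc[0]
        assert (row["gene_name"], row["chrom"], row["start"], row["end"]) == \
            ("GENE1", "2", 101, 900)

    def test_single_transcript_identity_apart_from_shift(self, tmp_path):
        p = tmp_path / "refgene.txt"
        p.write_text(self._flat([("NM_1", "chr7", "-", 1000, 2000, "ABC")]))
        row = read_refgene(p).iloc[0]
        assert (row["start"], row["end"], row["strand"]) == (1001, 2000, "-")

    def test_fixture_distinct_gene_count(self, tmp_path, cohort):
        g = read_refgene(cohort["files"]["refgene"])
        assert len(g) == cohort["genes"]["n_distinct_genes"]

    def test_unknown_source_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="source"):
            read_refgene(tmp_path / "x", source="gencode")


class TestPhasedVcf:
    def test_letter_and_code_conversion(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0|1\n")
        geno = read_phased_vcf(p, convert_letter=True)
        assert geno.haplotypes["S1"] == (["A"], ["G"])
        geno = read_phased_vcf(p, convert_letter=False)
        assert geno.haplotypes["S1"] == (["0"], ["1"])

    def test_unphased_genotype_rejected(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=1>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/1\n")
        with pytest.raises(ValueError, match="unphased"):
            read_phased_vcf(p)

    def test_fixture_reconstructs_planted_allele_matrix(self, cohort):
        geno = read_phased_vcf(cohort["files"]["vcf"], convert_letter=False)
        for sid, (h1, h2) in cohort["haplotypes"]["assignment"].items():
            assert "".join(geno.haplotypes[sid][0]) == h1
            assert "".join(geno.haplotypes[sid][1]) == h2
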