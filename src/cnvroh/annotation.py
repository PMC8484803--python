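"""Gene annotation of genomic intervals and sample-weighted gene frequency.

A gene is annotated to an interval iff the two share at least one base
pair on the same chromosome (strand ignored). Gene frequency is computed
from per-sample CNV annotations, not from CNVRs: a region hit in only one
or two samples should not lend its genes the apparent weight of the whole
region, so the carrier count for a gene is the number of distinct samples
whose own CNVs overlap it.
"""

from __future__ import annotations

import difflib
import logging

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

ANNOT_COLUMNS = ["interval_id", "gene_name", "chrom", "overlap_bp", "fully_contained"]


def _gene_trees(genes: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in genes.groupby("chrom"):
        t = IntervalTree()
        for row in sub.itertuples():
            # closed [start, end] stored as half-open [start, end+1)
            t.addi(row.start, row.end + 1, (row.gene_name, row.start, row.end))
        trees[chrom] = t
    return trees


def call_gene(intervals: pd.DataFrame, genes: pd.DataFrame,
              id_col: str = "interval_id") -> pd.DataFrame:
    """Annotate intervals with overlapping genes.

    Parameters
    ----------
    intervals
        Frame with ``chrom, start, end`` and an identifier column
        (``id_col``; falls back to the row index when absent).
    genes
        Cleaned gene list (``gene_name, chrom, start, end``).

    Returns one row per (interval, gene) pair sharing >=1 bp, with the
    overlap size and whether the gene is fully contained in the interval.
    """
    trees = _gene_trees(genes)
    rows = []
    ids = intervals[id_col] if id_col in intervals.columns else intervals.index
    for iid, chrom, start, end in zip(
            ids, intervals["chrom"], intervals["start"], intervals["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(start, end + 1),
                          key=lambda h: (h.begin, h.data[0])):
            gname, gstart, gend = hit.data
            ov = min(end, gend) - max(start, gstart) + 1
            rows.append({
                "interval_id": iid, "gene_name": gname, "chrom": chrom,
                "overlap_bp": ov,
                "fully_contained": bool(gstart >= start and gend <= end),
            })
    return pd.DataFrame(rows, columns=ANNOT_COLUMNS)


def annotate_intervals(intervals: pd.DataFrame, genes: pd.DataFrame,
                       id_col: str = "interval_id") -> pd.DataFrame:
    """Join :func:`call_gene` output back onto the interval rows.

    The result carries every interval column plus ``gene_name``,
    ``overlap_bp`` and ``fully_contained``; intervals without genes are
    absent.
    """
    df = intervals.copy()
    if id_col not in df.columns:
        df = df.reset_index().rename(columns={"index": id_col})
    annot = call_gene(df, genes, id_col=id_col)
    return annot.drop(columns="chrom").merge(df, on=id_col, how="left")


def gene_frequency(annotated_cnv: pd.DataFrame, sample_size: int) -> pd.DataFrame:
    """Per-gene carrier counts from CNV-level annotation.

    ``annotated_cnv`` must carry ``gene_name`` and ``sample_id`` (the
    output of :func:`annotate_intervals` on a clean per-sample CNV
    table). ``n_samples`` counts distinct carriers — a sample with two
    disjoint CNVs over one gene counts once. Sorted by descending
    carrier count, ties broken by gene name.
    """
    if sample_size <= 0:
        raise ValueError(f"sample_size must be positive, got {sample_size}")
    if "sample_id" not in annotated_cnv.columns:
        raise ValueError("gene_frequency needs per-sample CNV annotations "
                         "(missing sample_id column)")
    g = (annotated_cnv.groupby("gene_name")
         .agg(n_samples=("sample_id", "nunique"),
              n_cnv=("sample_id", "size"),
              chrom=("chrom", "first"))
         .reset_index())
    g["fraction_of_cohort"] = g["n_samples"] / sample_size
    g = g.sort_values(["n_samples", "gene_name"],
                      ascending=[False, True], kind="mergesort")
    return g.reset_index(drop=True)


def get_samples(annotated_cnv: pd.DataFrame, gene_name: str) -> pd.DataFrame:
    """All (sample, CNV) rows whose annotation includes ``gene_name``.

    Matching is case-sensitive (gene symbols are case-significant); on a
    miss an empty frame is returned and close lexical matches are logged.
    """
    hits = annotated_cnv[annotated_cnv["gene_name"] == gene_name]
    if len(hits) == 0:
        known = annotated_cnv["gene_name"].unique().tolist()
        # suggest case-insensitively: symbol case conventions differ by species
        lower_map = {}
        for k in known:
            lower_map.setdefault(k.lower(), k)
        close = [lower_map[m] for m in difflib.get_close_matches(
            gene_name.lower(), list(lower_map), n=3)]
        logger.warning("gene %r not found in annotation%s", gene_name,
                       f"; did you mean {close}?" if close else "")
        return hits.iloc[0:0]
    return hits.drop_duplicates().reset_index(drop=True)


def compare_gene(lists: dict[str, pd.DataFrame]
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build union and consensus tables from >=2 gene-frequency lists.

    Returns ``(union_table, consensus)``: the union table outer-joins on
    ``gene_name`` with one ``n_samples_<source>`` column per source and a
    ``present_in`` count; the consensus subset is the genes present in
    every source.
    """
    if len(lists) < 2:
        raise ValueError("compare_gene requires at least two gene lists")
    merged = None
    for name, df in lists.items():
        cols = df[["gene_name", "n_samples"]].rename(
            columns={"n_samples": f"n_samples_{name}"})
        merged = cols if merged is None else merged.merge(
            cols, on="gene_name", how="outer")
    count_cols = [c for c in merged.columns if c.startswith("n_samples_")]
    merged["present_in"] = merged[count_cols].notna().sum(axis=1)
    merged = merged.sort_values(
        ["present_in", "gene_name"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    consensus = merged[merged["present_in"] == len(lists)].reset_index(drop=True)
    return merged, consensus


def gene_symbol_export(freq: pd.DataFrame, path) -> None:
    """One-column gene-symbol list, directly loadable by annotation tools
    such as DAVID."""
    freq["gene_name"].to_csv(path, index=False, header=False)
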