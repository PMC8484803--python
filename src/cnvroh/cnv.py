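"""Standardize raw CNV calls and build the summary cross-tabulations.

A standardized CNV table has one row per copy-number call with 1-based
closed coordinates, a two-valued type (deletion for copy number < 2,
duplication for > 2), and the call length in bp. Copy-neutral calls
(cn = 2) are not CNVs and are dropped at the cleaning step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from cnvroh._util import (
    assign_length_group,
    is_recognized_chrom,
    normalize_chrom,
    sort_by_chrom,
)
from cnvroh.formats_io import RawCnvRecord

logger = logging.getLogger(__name__)

#: Default length-group boundaries in bp (user-overridable).
DEFAULT_LENGTH_BREAKS = (0, 100_000, 500_000, 1_000_000, 5_000_000, float("inf"))

CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "cn", "cnv_type",
               "length", "n_snps", "confidence"]


@dataclass
class CleanReport:
    """Bookkeeping from :func:`clean_cnv`."""

    n_input: int = 0
    n_output: int = 0
    dropped_cn2: int = 0
    dropped_chrom: int = 0
    dropped_chrom_labels: list[str] = field(default_factory=list)


def cnv_type_of(cn: int) -> str:
    return "deletion" if cn < 2 else "duplication"


def clean_cnv(records) -> tuple[pd.DataFrame, CleanReport]:
    """Standardize raw CNV records into the clean CNV table.

    Normalizes chromosome labels, drops copy-neutral (cn = 2) calls and
    calls on unrecognized chromosomes (both counted in the report),
    assigns deletion/duplication type and bp length, and sorts by
    (sample, chromosome, start). Idempotent: re-cleaning an already clean
    table is the identity.

    Accepts either an iterable of :class:`~cnvroh.formats_io.RawCnvRecord`
    or an already-standardized DataFrame.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [r for r in records]
        df = pd.DataFrame({
            "sample_id": [r.sample_id for r in rows],
            "chrom": [r.chrom for r in rows],
            "start": [r.start_bp for r in rows],
            "end": [r.end_bp for r in rows],
            "cn": [r.copy_number for r in rows],
            "n_snps": [r.num_snps for r in rows],
            "confidence": [r.confidence for r in rows],
        })
    report = CleanReport(n_input=len(df))
    if len(df) == 0:
        logger.warning("clean_cnv: empty input")
        empty = pd.DataFrame(columns=CNV_COLUMNS)
        return empty, report

    df["chrom"] = df["chrom"].map(normalize_chrom)
    bad_chrom = ~df["chrom"].map(is_recognized_chrom)
    report.dropped_chrom = int(bad_chrom.sum())
    report.dropped_chrom_labels = sorted(df.loc[bad_chrom, "chrom"].unique())
    df = df[~bad_chrom]

    cn2 = df["cn"] == 2
    report.dropped_cn2 = int(cn2.sum())
    df = df[~cn2].copy()

    df["cnv_type"] = df["cn"].map(cnv_type_of)
    df["length"] = df["end"] - df["start"] + 1
    if "n_snps" not in df.columns:
        df["n_snps"] = pd.NA
    if "confidence" not in df.columns:
        df["confidence"] = pd.NA

    df = df.sort_values("sample_id", kind="mergesort")
    df = sort_by_chrom(df, extra_cols=["start"])
    df = df.sort_values("sample_id", kind="mergesort").reset_index(drop=True)
    df = df[CNV_COLUMNS]
    report.n_output = len(df)
    if report.n_output == 0:
        logger.warning("clean_cnv: no CNVs left after filtering "
                       "(%d cn=2, %d bad chromosome)",
                       report.dropped_cn2, report.dropped_chrom)
    return df, report


@dataclass
class CnvSummary:
    """The four cross-tabulations behind the brief CNV summary table.

    Every marginal total equals the number of CNV rows summarized.
    """

    by_length_type: pd.DataFrame    # length_group x cnv_type: count, total bp
    by_chrom_type: pd.DataFrame     # chrom x cnv_type: count, total bp
    by_state: pd.DataFrame          # copy-number state: count
    by_sample: pd.DataFrame         # sample: count, total bp
    n_cnv: int

    def brief_table(self) -> pd.DataFrame:
        """Length-group x type counts in wide layout with margins."""
        wide = self.by_length_type.pivot_table(
            index="length_group", columns="cnv_type", values="count",
            aggfunc="sum", fill_value=0, observed=False)
        wide["total"] = wide.sum(axis=1)
        return wide.reset_index()


def summarize_cnv(cnv: pd.DataFrame,
                  length_breaks=DEFAULT_LENGTH_BREAKS) -> CnvSummary:
    """Cross-tabulate a clean CNV table by length group, type, chromosome,
    copy-number state and sample.

    Length groups are half-open bins ``[b_i, b_{i+1})`` over the supplied
    strictly-increasing break sequence.
    """
    if len(cnv) == 0:
        raise ValueError("summarize_cnv requires a non-empty CNV table")
    df = cnv.copy()
    df["length_group"] = assign_length_group(df["length"], length_breaks)

    by_lt = (df.groupby(["length_group", "cnv_type"], observed=False)
             .agg(count=("length", "size"), total_bp=("length", "sum"))
             .reset_index())
    by_ct = (df.groupby(["chrom", "cnv_type"], observed=False)
             .agg(count=("length", "size"), total_bp=("length", "sum"))
             .reset_index())
    by_ct = sort_by_chrom(by_ct)
    by_state = (df.groupby("cn").size().rename("count").reset_index()
                .sort_values("cn").reset_index(drop=True))
    by_sample = (df.groupby("sample_id")
                 .agg(count=("length", "size"), total_bp=("length", "sum"))
                 .reset_index().sort_values("sample_id").reset_index(drop=True))
    return CnvSummary(by_lt, by_ct, by_state, by_sample, n_cnv=len(df))
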