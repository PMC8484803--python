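"""CNVR calling: merge per-sample CNVs into copy number variation regions.

A CNVR is the union of a maximal set of CNVs, from any samples, that are
chained together by pairwise overlap of at least one base pair (closed
1-based intervals, so ``[100,200]`` and ``[200,300]`` share base 200 and
merge, while the bookended pair ``[100,200]``/``[201,300]`` does not).
Regions are typed Deletion / Duplication / Mixed, where Mixed means both
deletions and duplications occur among the member CNVs.
"""

from __future__ import annotations

import pandas as pd

from cnvroh._util import assign_length_group, chrom_sort_key, sort_by_chrom
from cnvroh.cnv import DEFAULT_LENGTH_BREAKS

CNVR_COLUMNS = ["cnvr_id", "chrom", "start", "end", "length",
                "n_cnv", "n_samples", "n_del", "n_dup", "cnvr_type"]

#: Conventional "common variant" frequency cutoff; user-overridable.
DEFAULT_COMMON_CNV_THRESHOLD = 0.05


def classify_cnvr(copy_numbers) -> str:
    """Region type from member copy numbers: Deletion if all < 2,
    Duplication if all > 2, Mixed otherwise."""
    cns = list(copy_numbers)
    if not cns:
        raise ValueError("classify_cnvr requires at least one member CNV")
    if all(cn < 2 for cn in cns):
        return "Deletion"
    if all(cn > 2 for cn in cns):
        return "Duplication"
    return "Mixed"


def call_cnvr(cnv: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Merge overlapping CNVs into CNVRs by a per-chromosome sweep.

    Parameters
    ----------
    cnv
        Clean CNV table (``sample_id, chrom, start, end, cn, ...``).

    Returns
    -------
    (cnvr, membership)
        ``cnvr`` has one row per region with member counts (total,
        distinct samples, per type) and its Deletion/Duplication/Mixed
        type; ``cnvr_id`` is ``CNVR_<chrom>_<ordinal>`` in coordinate
        order. ``membership`` maps each input row's index to its
        ``cnvr_id`` (a total function: every CNV lands in exactly one
        region).
    """
    if len(cnv) == 0:
        empty = pd.DataFrame(columns=CNVR_COLUMNS)
        return empty, pd.Series(dtype=object, name="cnvr_id")

    membership = pd.Series(index=cnv.index, dtype=object, name="cnvr_id")
    rows = []
    for chrom in sorted(cnv["chrom"].unique(), key=chrom_sort_key):
        sub = cnv[cnv["chrom"] == chrom].sort_values(
            ["start", "end"], kind="mergesort")
        ordinal = 0
        cur_idx: list = []
        cur_start = cur_end = None

        def flush():
            nonlocal ordinal
            ordinal += 1
            cnvr_id = f"CNVR_{chrom}_{ordinal}"
            members = cnv.loc[cur_idx]
            membership.loc[cur_idx] = cnvr_id
            rows.append({
                "cnvr_id": cnvr_id, "chrom": chrom,
                "start": cur_start, "end": cur_end,
                "length": cur_end - cur_start + 1,
                "n_cnv": len(cur_idx),
                "n_samples": members["sample_id"].nunique(),
                "n_del": int((members["cn"] < 2).sum()),
                "n_dup": int((members["cn"] > 2).sum()),
                "cnvr_type": classify_cnvr(members["cn"]),
            })

        for idx, start, end in zip(sub.index, sub["start"], sub["end"]):
            if cur_idx and start <= cur_end:          # >=1 shared bp
                cur_idx.append(idx)
                cur_end = max(cur_end, end)
            else:
                if cur_idx:
                    flush()
                cur_idx = [idx]
                cur_start, cur_end = start, end
        if cur_idx:
            flush()

    cnvr = pd.DataFrame(rows, columns=CNVR_COLUMNS)
    return cnvr, membership


def cnvr_summaries(cnvr: pd.DataFrame,
                   length_breaks=DEFAULT_LENGTH_BREAKS
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Brief summary (length group x type counts) and per-chromosome
    count/total-length table for a CNVR list."""
    if len(cnvr) == 0:
        brief = pd.DataFrame(columns=["length_group", "cnvr_type", "count"])
        per_chrom = pd.DataFrame(columns=["chrom", "count", "total_length_bp"])
        return brief, per_chrom
    df = cnvr.copy()
    df["length_group"] = assign_length_group(df["length"], length_breaks)
    brief = (df.groupby(["length_group", "cnvr_type"], observed=False)
             .size().rename("count").reset_index())
    per_chrom = (df.groupby("chrom")
                 .agg(count=("length", "size"), total_length_bp=("length", "sum"))
                 .reset_index())
    per_chrom = sort_by_chrom(per_chrom)
    return brief, per_chrom


def high_freq_cnvr(cnvr: pd.DataFrame, sample_size: int,
                   common_cnv_threshold: float = DEFAULT_COMMON_CNV_THRESHOLD
                   ) -> pd.DataFrame:
    """Select CNVRs whose carrier frequency n_samples/sample_size meets
    the common-CNV threshold. Order is preserved; a ``freq`` column is
    added."""
    if not (0 < common_cnv_threshold <= 1):
        raise ValueError(
            f"common_cnv_threshold must be in (0, 1], got {common_cnv_threshold}")
    if len(cnvr) and sample_size < cnvr["n_samples"].max():
        raise ValueError(
            f"sample_size {sample_size} is smaller than the largest CNVR "
            f"carrier count {cnvr['n_samples'].max()}")
    out = cnvr.copy()
    out["freq"] = out["n_samples"] / sample_size
    return out[out["freq"] >= common_cnv_threshold].reset_index(drop=True)


def cnvr_to_bed(cnvr: pd.DataFrame) -> pd.DataFrame:
    """BED view of a CNVR table (0-based half-open) for genome browsers."""
    return pd.DataFrame({
        "chrom": cnvr["chrom"],
        "chromStart": cnvr["start"] - 1,
        "chromEnd": cnvr["end"],
        "name": cnvr["cnvr_id"],
    })
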