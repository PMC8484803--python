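"""Compare two interval sets at population and individual level.

Population-level comparison asks whether a region found in one study was
found at all in the other; individual-level comparison additionally
requires the same sample to carry both calls, which probes the robustness
of the detection algorithms rather than the ubiquity of the regions.
A single long interval in one set may overlap several shorter ones in the
other, so a lone "overlap count" is ambiguous; reports here carry
A-anchored and B-anchored counts, a multiplicity histogram, and a
merged-region count of the overlapping material.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from cnvroh._util import normalize_chrom

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["id_a", "id_b", "chrom", "start_a", "end_a", "start_b", "end_b",
                "overlap_bp", "frac_of_a", "frac_of_b"]


@dataclass
class ComparisonReport:
    """Summary of an interval-set comparison, recomputable from the pair
    list plus the two set sizes."""

    n_a: int
    n_b: int
    n_pairs: int
    overlapping_a: int          # intervals in A hitting >=1 in B
    overlapping_b: int
    unique_a: int
    unique_b: int
    multiplicity_a: dict[int, int]   # hits-per-A-interval histogram
    multiplicity_b: dict[int, int]
    n_merged_regions: int       # connected components of the overlap graph
    total_overlap_bp: int
    mean_frac_a: float          # mean fraction of A intervals covered (over pairs)
    mean_frac_b: float

    def as_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items()
             if not isinstance(v, dict)}
        return pd.DataFrame([d])


def _prepare(df: pd.DataFrame, label: str, need_sample: bool) -> pd.DataFrame:
    out = df.copy()
    if "id" not in out.columns:
        out["id"] = [f"{label}{i}" for i in range(len(out))]
    if need_sample and "sample_id" not in out.columns:
        raise ValueError(f"match_sample=True but set {label} has no sample_id")
    chroms = out["chrom"].astype(str)
    if chroms.str.lower().str.startswith("chr").any():
        logger.warning("set %s uses 'chr'-prefixed chromosome names; normalizing", label)
    out["chrom"] = chroms.map(normalize_chrom)
    return out


def _report_from_pairs(pairs: pd.DataFrame, a: pd.DataFrame,
                       b: pd.DataFrame) -> ComparisonReport:
    n_a, n_b = len(a), len(b)
    if len(pairs) == 0:
        return ComparisonReport(n_a, n_b, 0, 0, 0, n_a, n_b, {}, {}, 0, 0, 0.0, 0.0)
    per_a = pairs.groupby("id_a").size()
    per_b = pairs.groupby("id_b").size()
    # merged-region count: connected components of the bipartite overlap graph
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for ia, ib in zip(pairs["id_a"], pairs["id_b"]):
        union(("a", ia), ("b", ib))
    n_merged = len({find(k) for k in parent})
    return ComparisonReport(
        n_a=n_a, n_b=n_b, n_pairs=len(pairs),
        overlapping_a=int(per_a.size), overlapping_b=int(per_b.size),
        unique_a=n_a - int(per_a.size), unique_b=n_b - int(per_b.size),
        multiplicity_a={int(k): int(v) for k, v in
                        per_a.value_counts().sort_index().items()},
        multiplicity_b={int(k): int(v) for k, v in
                        per_b.value_counts().sort_index().items()},
        n_merged_regions=n_merged,
        total_overlap_bp=int(pairs["overlap_bp"].sum()),
        mean_frac_a=float(pairs["frac_of_a"].mean()),
        mean_frac_b=float(pairs["frac_of_b"].mean()),
    )


def compare_interval(a: pd.DataFrame, b: pd.DataFrame,
                     match_sample: bool = False
                     ) -> tuple[pd.DataFrame, ComparisonReport]:
    """Find all >=1 bp overlaps between interval sets A and B.

    Both frames need ``chrom, start, end`` (1-based closed) and optionally
    ``id`` and ``sample_id`` columns. With ``match_sample=True`` a pair is
    only emitted when the two intervals belong to the same sample
    (individual-level comparison). Pairs are ordered by
    (chrom, start_a, start_b).
    """
    a = _prepare(a, "A", match_sample)
    b = _prepare(b, "B", match_sample)

    trees: dict[str, IntervalTree] = {}
    for row in b.itertuples():
        key = row.chrom
        trees.setdefault(key, IntervalTree()).addi(
            row.start, row.end + 1,
            (row.id, row.start, row.end,
             getattr(row, "sample_id", None)))
    rows = []
    for row in a.itertuples():
        tree = trees.get(row.chrom)
        if tree is None:
            continue
        sa = getattr(row, "sample_id", None)
        for hit in tree.overlap(row.start, row.end + 1):
            id_b, sb, eb, samp_b = hit.data
            if match_sample and sa != samp_b:
                continue
            ov = min(row.end, eb) - max(row.start, sb) + 1
            rows.append({
                "id_a": row.id, "id_b": id_b, "chrom": row.chrom,
                "start_a": row.start, "end_a": row.end,
                "start_b": sb, "end_b": eb,
                "overlap_bp": ov,
                "frac_of_a": ov / (row.end - row.start + 1),
                "frac_of_b": ov / (eb - sb + 1),
            })
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if len(pairs):
        pairs = pairs.sort_values(
            ["chrom", "start_a", "start_b", "id_a", "id_b"],
            kind="mergesort").reset_index(drop=True)
    return pairs, _report_from_pairs(pairs, a, b)


@dataclass
class CnvComparison:
    population_pairs: pd.DataFrame
    population: ComparisonReport
    individual_pairs: pd.DataFrame
    individual: ComparisonReport
    by_type: pd.DataFrame | None = None   # (cnv_type_a x cnv_type_b) pair counts


def compare_cnv(a: pd.DataFrame, b: pd.DataFrame,
                by_type: bool = False) -> CnvComparison:
    """Compare two clean CNV tables on a population and individual basis.

    With ``by_type=True`` population-level pairs are additionally
    stratified into a deletion/duplication 2x2 count table.
    """
    a = a.reset_index(drop=True).copy()
    b = b.reset_index(drop=True).copy()
    if "id" not in a.columns:
        a["id"] = [f"A{i}" for i in range(len(a))]
    if "id" not in b.columns:
        b["id"] = [f"B{i}" for i in range(len(b))]
    pop_pairs, pop = compare_interval(a, b, match_sample=False)
    ind_pairs, ind = compare_interval(a, b, match_sample=True)
    type_tab = None
    if by_type:
        ta = a.set_index("id")["cnv_type"]
        tb = b.set_index("id")["cnv_type"]
        tmp = pop_pairs.assign(cnv_type_a=pop_pairs["id_a"].map(ta),
                               cnv_type_b=pop_pairs["id_b"].map(tb))
        type_tab = (tmp.groupby(["cnv_type_a", "cnv_type_b"])
                    .size().rename("n_pairs").reset_index())
    return CnvComparison(pop_pairs, pop, ind_pairs, ind, type_tab)


def compare_cnvr(a: pd.DataFrame, b: pd.DataFrame
                 ) -> tuple[pd.DataFrame, ComparisonReport]:
    """Population-level comparison of two CNVR lists."""
    a = a.rename(columns={"cnvr_id": "id"})
    b = b.rename(columns={"cnvr_id": "id"})
    return compare_interval(a, b, match_sample=False)
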