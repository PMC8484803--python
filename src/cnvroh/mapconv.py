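"""SNP-map reconciliation between assemblies and SNP-anchored liftover.

Two SNP maps from the same genotyping chip but different reference
assemblies are matched by marker name; the matched table then drives an
interval liftover that uses only the markers' target positions — no
positions are interpolated or invented. Marker order can change between
assemblies, markers can move chromosome or disappear, so the conversion
reports length changes, order inversions and split-chromosome failures
rather than assuming a clean mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MATCH_CLASSES = ("same_chr", "chr_changed", "missing_in_target", "missing_in_default")

#: Fail conversion when more than this fraction of in-interval SNPs map to
#: a different chromosome than the modal one.
DEFAULT_MINORITY_TOLERANCE = 0.10

CONVERTED_MAP_COLUMNS = ["snp_name", "chrom_default", "pos_default",
                         "chrom_target", "pos_target", "match_class"]


class MapMismatchError(ValueError):
    """The two maps share no SNP names — they are not from the same chip."""


def convert_map(default_map: pd.DataFrame, target_map: pd.DataFrame):
    """Match two SNP maps by marker name.

    Parameters
    ----------
    default_map, target_map
        Frames with ``snp_name, chrom, pos`` (from
        :func:`cnvroh.formats_io.read_snp_map`).

    Returns
    -------
    (converted, summary, densities)
        ``converted`` is the full outer join with a ``match_class`` per
        marker; ``summary`` counts markers per class; ``densities`` holds
        per-chromosome SNP density tables for both maps.
    """
    d = default_map.rename(columns={"chrom": "chrom_default", "pos": "pos_default"})
    t = target_map.rename(columns={"chrom": "chrom_target", "pos": "pos_target"})
    merged = d.merge(t, on="snp_name", how="outer")
    has_d = merged["pos_default"].notna()
    has_t = merged["pos_target"].notna()
    if not (has_d & has_t).any():
        raise MapMismatchError(
            "the two maps share no SNP names; coordinates can only be "
            "converted between maps of the same SNP chip")
    cls = np.select(
        [has_d & has_t & (merged["chrom_default"] == merged["chrom_target"]),
         has_d & has_t,
         has_d & ~has_t],
        ["same_chr", "chr_changed", "missing_in_target"],
        default="missing_in_default")
    merged["match_class"] = cls
    # keep default-map order first, appended target-only markers after
    merged = merged.sort_values(
        ["match_class"], key=lambda s: s.eq("missing_in_default"),
        kind="mergesort").reset_index(drop=True)
    merged = merged[CONVERTED_MAP_COLUMNS]
    summary = (merged["match_class"].value_counts()
               .reindex(MATCH_CLASSES, fill_value=0)
               .rename_axis("match_class").reset_index(name="n_snps"))
    densities = {
        "default": snp_density(default_map),
        "target": snp_density(target_map),
    }
    return merged, summary, densities


def snp_density(map_df: pd.DataFrame) -> pd.DataFrame:
    """Per-chromosome SNP density: count, covered span and mean gap.

    ``mean_gap_bp = span / (n_snps - 1)``; chromosomes with fewer than two
    markers get NaN and ``degenerate=True``.
    """
    rows = []
    for chrom, sub in map_df.groupby("chrom"):
        n = len(sub)
        span = int(sub["pos"].max() - sub["pos"].min())
        rows.append({
            "chrom": chrom, "n_snps": n, "span_bp": span,
            "mean_gap_bp": span / (n - 1) if n >= 2 else float("nan"),
            "degenerate": n < 2,
        })
    return pd.DataFrame(rows, columns=["chrom", "n_snps", "span_bp",
                                       "mean_gap_bp", "degenerate"])


@dataclass
class ConversionSummary:
    n_intervals: int
    n_converted: int
    n_failed: int
    failures_by_reason: dict[str, int]
    n_order_inverted: int
    n_chromosome_changed: int
    mean_length_delta: float
    max_abs_length_delta: int

    def as_frame(self) -> pd.DataFrame:
        d = {k: v for k, v in self.__dict__.items() if not isinstance(v, dict)}
        return pd.DataFrame([d])


RESULT_COLUMNS = ["interval_id", "chrom", "start", "end", "length_interval",
                  "converted", "chrom_target", "start_target", "end_target",
                  "length_default", "length_target", "length_delta",
                  "n_snps_used", "n_snps_dropped", "order_inverted",
                  "chromosome_changed", "failure_reason"]


def convert_coord(intervals: pd.DataFrame, converted_map: pd.DataFrame,
                  minority_tolerance: float = DEFAULT_MINORITY_TOLERANCE
                  ) -> tuple[pd.DataFrame, ConversionSummary]:
    """Lift intervals from the default assembly to the target via matched
    SNPs.

    For each interval, the markers whose default position falls inside it
    and that carry a target position are collected; the target chromosome
    is the modal chromosome among them (ties broken toward the default
    chromosome, else lexicographically); the converted interval is the
    [min, max] span of the retained markers' target positions. Fails with
    ``no_snps_in_interval`` when the interval contains no usable marker,
    or ``snps_split_across_chromosomes`` when more than
    ``minority_tolerance`` of its markers map off the modal chromosome.
    ``order_inverted`` flags intervals whose marker order is not monotone
    between assemblies.
    """
    if len(converted_map) == 0:
        raise ValueError("converted_map is empty; run convert_map first")
    usable = converted_map[
        converted_map["match_class"].isin(["same_chr", "chr_changed"])
        & converted_map["pos_target"].notna()].copy()
    usable["pos_default"] = usable["pos_default"].astype(int)
    usable["pos_target"] = usable["pos_target"].astype(int)

    by_chrom = {c: sub.sort_values("pos_default")
                for c, sub in usable.groupby("chrom_default")}
    ints = intervals.copy()
    if "interval_id" not in ints.columns:
        ints = ints.reset_index().rename(columns={"index": "interval_id"})

    rows = []
    for row in ints.itertuples():
        rec = {
            "interval_id": row.interval_id, "chrom": str(row.chrom),
            "start": row.start, "end": row.end,
            "length_interval": row.end - row.start + 1, "converted": False,
            "chrom_target": None, "start_target": None, "end_target": None,
            "length_default": None,
            "length_target": None, "length_delta": None,
            "n_snps_used": 0, "n_snps_dropped": 0,
            "order_inverted": False, "chromosome_changed": False,
            "failure_reason": None,
        }
        sub = by_chrom.get(str(row.chrom))
        if sub is not None:
            sub = sub[(sub["pos_default"] >= row.start)
                      & (sub["pos_default"] <= row.end)]
        if sub is None or len(sub) == 0:
            rec["failure_reason"] = "no_snps_in_interval"
            rows.append(rec)
            continue
        counts = sub["chrom_target"].value_counts()
        top = counts.max()
        modal_cands = sorted(counts[counts == top].index)
        modal = (str(row.chrom) if str(row.chrom) in modal_cands
                 else modal_cands[0])
        kept = sub[sub["chrom_target"] == modal]
        dropped = len(sub) - len(kept)
        if dropped > minority_tolerance * len(sub):
            rec["failure_reason"] = "snps_split_across_chromosomes"
            rec["n_snps_dropped"] = dropped
            rows.append(rec)
            continue
        tpos = kept["pos_target"].to_numpy()
        dpos = kept["pos_default"].to_numpy()
        rec.update({
            "converted": True, "chrom_target": modal,
            "start_target": int(tpos.min()), "end_target": int(tpos.max()),
            # lengths are marker-anchored spans on each assembly, so the
            # delta isolates what the assembly change did to the region
            "length_default": int(dpos.max() - dpos.min() + 1),
            "length_target": int(tpos.max() - tpos.min() + 1),
            "n_snps_used": len(kept), "n_snps_dropped": dropped,
            # kept is sorted by default position; check target monotonicity
            "order_inverted": bool(
                not (np.all(np.diff(tpos) >= 0) or np.all(np.diff(tpos) <= 0))
                or (len(tpos) > 1 and tpos[0] > tpos[-1])),
            "chromosome_changed": modal != str(row.chrom),
        })
        rec["length_delta"] = rec["length_target"] - rec["length_default"]
        rows.append(rec)

    res = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    conv = res[res["converted"]]
    fails = res.loc[~res["converted"], "failure_reason"].value_counts()
    summary = ConversionSummary(
        n_intervals=len(res), n_converted=len(conv),
        n_failed=len(res) - len(conv),
        failures_by_reason={str(k): int(v) for k, v in fails.items()},
        n_order_inverted=int(conv["order_inverted"].sum()),
        n_chromosome_changed=int(conv["chromosome_changed"].sum()),
        mean_length_delta=(float(conv["length_delta"].mean())
                           if len(conv) else float("nan")),
        max_abs_length_delta=(int(conv["length_delta"].abs().max())
                              if len(conv) else 0),
    )
    return res, summary


def converted_to_target_map(converted: pd.DataFrame) -> pd.DataFrame:
    """Target-assembly view of a converted map, in PLINK ``.map`` column
    layout (drop markers missing in the target)."""
    ok = converted[converted["pos_target"].notna()]
    return pd.DataFrame({
        "snp_name": ok["snp_name"],
        "chrom": ok["chrom_target"],
        "pos": ok["pos_target"].astype(int),
    }).reset_index(drop=True)
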