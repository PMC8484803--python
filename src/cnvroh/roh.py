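"""ROH summaries, ROH-based inbreeding coefficients and high-frequency
ROH region detection.

The inbreeding coefficient is F_roh = (sum L_roh) / (sum L_auto): the
total autosomal ROH length of an individual divided by the total autosome
length. Because ROH of different lengths reflect inbreeding at different
time depths (long ROH: recent; short ROH: ancient), F_roh is also
decomposed into disjoint length-group components that sum exactly to the
total.

High-frequency detection is anchored on the SNP map rather than fixed-bp
windows: per map marker, the fraction of individuals whose ROH span it is
counted, and maximal runs of consecutive markers at or above the
frequency threshold become regions. This respects uneven marker density,
which strongly affects ROH inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cnvroh._util import assign_length_group, is_autosome, sort_by_chrom

#: Standard ROH length classes in bp (0-2, 2-4, 4-8, 8-16, >16 Mb).
DEFAULT_ROH_LENGTH_BREAKS = (0, 2_000_000, 4_000_000, 8_000_000,
                             16_000_000, float("inf"))

DEFAULT_ROH_FREQ_THRESHOLD = 0.3


def _roh_lengths(roh: pd.DataFrame) -> pd.Series:
    if "length_bp" in roh.columns:
        return roh["length_bp"]
    return roh["end"] - roh["start"] + 1


def roh_length_summary(roh: pd.DataFrame,
                       length_breaks=DEFAULT_ROH_LENGTH_BREAKS) -> pd.DataFrame:
    """Counts and total lengths of ROH per half-open length group."""
    if len(roh) == 0:
        return pd.DataFrame(columns=["length_group", "count", "total_bp"])
    df = roh.copy()
    df["length_bp"] = _roh_lengths(df)
    df["length_group"] = assign_length_group(df["length_bp"], length_breaks)
    return (df.groupby("length_group", observed=False)
            .agg(count=("length_bp", "size"), total_bp=("length_bp", "sum"))
            .reset_index())


def autosome_lengths_from_map(map_df: pd.DataFrame) -> dict[str, int]:
    """Chip-covered autosome lengths (max - min marker position + 1) —
    the reproducible denominator for F_roh when true assembly lengths are
    not supplied."""
    out = {}
    for chrom, sub in map_df.groupby("chrom"):
        if is_autosome(chrom):
            out[str(chrom)] = int(sub["pos"].max() - sub["pos"].min() + 1)
    return out


def froh(roh: pd.DataFrame, autosome_lengths: dict[str, int],
         length_breaks=DEFAULT_ROH_LENGTH_BREAKS,
         samples=None) -> pd.DataFrame:
    """Per-individual F_roh = (sum L_roh) / (sum L_auto), total and by
    length group.

    Parameters
    ----------
    roh
        ROH table; non-autosomal segments are excluded.
    autosome_lengths
        chrom -> length in bp; must cover every autosome with ROH.
    samples
        Optional full cohort; individuals without ROH get F_roh = 0.

    The per-length-group components are computed on disjoint bins and sum
    exactly to the total.
    """
    auto = {str(k): int(v) for k, v in autosome_lengths.items()}
    sum_l_auto = sum(auto.values())
    if sum_l_auto <= 0:
        raise ValueError("total autosome length must be positive")
    df = roh.copy()
    df = df[df["chrom"].astype(str).map(is_autosome)]
    missing = sorted(set(df["chrom"].astype(str)) - set(auto))
    if missing:
        raise ValueError(
            f"ROH present on chromosomes absent from autosome_lengths: {missing}")
    df["length_bp"] = _roh_lengths(df)
    df["length_group"] = assign_length_group(df["length_bp"], length_breaks)

    ids = list(samples) if samples is not None else sorted(df["sample_id"].unique())
    ids = sorted(set(ids) | set(df["sample_id"].unique())) if samples is not None else ids

    totals = df.groupby("sample_id")["length_bp"].sum()
    rows = []
    group_labels = assign_length_group([1], length_breaks).categories
    per_group = df.pivot_table(index="sample_id", columns="length_group",
                               values="length_bp", aggfunc="sum",
                               fill_value=0, observed=False)
    for sid in ids:
        l_roh = int(totals.get(sid, 0))
        row = {"sample_id": sid,
               "sum_l_roh_bp": l_roh,
               "sum_l_auto_bp": sum_l_auto,
               "f_roh_total": l_roh / sum_l_auto}
        for g in group_labels:
            gl = int(per_group.loc[sid, g]) if sid in per_group.index else 0
            row[f"f_roh_{g}"] = gl / sum_l_auto
        rows.append(row)
    return pd.DataFrame(rows)


def roh_incidence(roh: pd.DataFrame, map_df: pd.DataFrame,
                  n_individuals: int | None = None) -> pd.DataFrame:
    """Per-marker ROH carrier counts on the autosomes.

    For each map marker, counts the distinct individuals with at least
    one ROH spanning its position (closed intervals). The frequency
    denominator defaults to the number of distinct individuals in the ROH
    table; pass ``n_individuals`` to use the full genotyped cohort
    instead.
    """
    if n_individuals is None:
        n_individuals = roh["sample_id"].nunique()
    snps = map_df[map_df["chrom"].astype(str).map(is_autosome)]
    snps = sort_by_chrom(snps, extra_cols=["pos"])
    out_rows = []
    roh_auto = roh[roh["chrom"].astype(str).map(is_autosome)]
    by_chrom = dict(tuple(roh_auto.groupby(roh_auto["chrom"].astype(str))))
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        counts = np.zeros(len(pos), dtype=int)
        segs = by_chrom.get(str(chrom))
        if segs is not None:
            order = np.argsort(pos, kind="mergesort")
            sorted_pos = pos[order]
            # accumulate per-sample coverage via +-1 difference counting
            for _, person in segs.groupby("sample_id"):
                covered = np.zeros(len(pos) + 1, dtype=int)
                for s, e in zip(person["start"], person["end"]):
                    lo = np.searchsorted(sorted_pos, s, side="left")
                    hi = np.searchsorted(sorted_pos, e, side="right")
                    covered[lo] += 1
                    covered[hi] -= 1
                counts[order] += (np.cumsum(covered[:-1]) > 0).astype(int)
        for p, c, name in zip(pos, counts, sub["snp_name"]):
            out_rows.append({"chrom": chrom, "pos": int(p), "snp_name": name,
                             "n_carriers": int(c),
                             "freq": c / n_individuals if n_individuals else 0.0})
    out = pd.DataFrame(out_rows,
                       columns=["chrom", "pos", "snp_name", "n_carriers", "freq"])
    out.attrs["n_individuals"] = n_individuals
    return out


def high_freq_roh(incidence: pd.DataFrame,
                  threshold: float = DEFAULT_ROH_FREQ_THRESHOLD) -> pd.DataFrame:
    """Maximal runs of consecutive map markers with ROH frequency at or
    above the threshold.

    Region bounds are the first/last marker positions of the run; peak
    and mean frequency over the run are reported. Extending any region by
    one flanking marker would drop it below the threshold.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    rows = []
    for chrom, sub in incidence.groupby("chrom", sort=False):
        sub = sub.sort_values("pos", kind="mergesort")
        run = []
        for pos, freq in zip(sub["pos"], sub["freq"]):
            if freq >= threshold:
                run.append((pos, freq))
            elif run:
                rows.append(_region_row(chrom, run))
                run = []
        if run:
            rows.append(_region_row(chrom, run))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps_in_region",
                                       "peak_freq", "mean_freq"])


def _region_row(chrom, run):
    freqs = [f for _, f in run]
    return {"chrom": chrom, "start": run[0][0], "end": run[-1][0],
            "n_snps_in_region": len(run),
            "peak_freq": max(freqs), "mean_freq": sum(freqs) / len(freqs)}
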