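"""Plot-data preparation and rendering.

Every figure is built in two stages: a ``prepare_*`` function produces a
:class:`PlotSpec` holding plain tables (the testable data layer), and
:func:`render` draws a spec with matplotlib without recomputing anything.
The same spec therefore always yields the same drawing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from cnvroh._util import chrom_sort_key

#: Copy-number state colors: homozygous/heterozygous deletion in reds,
#: single/multi-copy gain in blues. Overridable per spec.
DEFAULT_CN_COLORS = {0: "#8b0000", 1: "#e06666", 3: "#6fa8dc", 4: "#1c4587"}
DEFAULT_CNVR_COLORS = {"Deletion": "#c0392b", "Duplication": "#2e86c1",
                       "Mixed": "#8e44ad"}
ROH_COLOR = "#2c7a3f"
GENE_COLOR = "#555555"


@dataclass
class PlotSpec:
    """Prepared, render-ready data for one plot."""

    kind: str   # cnv_summary | cnvr_map | cnv_region | roh_region | roh_frequency | snp_density
    tables: dict[str, pd.DataFrame]
    style: dict = field(default_factory=dict)


def _assign_lanes(df: pd.DataFrame) -> pd.DataFrame:
    """First-fit lane assignment by sorted start: rows in one lane never
    overlap."""
    df = df.sort_values(["start", "end"], kind="mergesort").copy()
    lane_ends: list[int] = []
    lanes = []
    for s, e in zip(df["start"], df["end"]):
        for i, le in enumerate(lane_ends):
            if s > le:
                lanes.append(i)
                lane_ends[i] = e
                break
        else:
            lanes.append(len(lane_ends))
            lane_ends.append(e)
    df["lane"] = lanes
    return df.reset_index(drop=True)


def prepare_region_tracks(table: pd.DataFrame, region: tuple,
                          genes: pd.DataFrame | None = None,
                          kind: str = "cnv_region",
                          style: dict | None = None) -> PlotSpec:
    """Stacked-interval view of CNVs or ROH in one region.

    ``region`` is ``(chrom, start_mb, end_mb)``. Intervals are clipped to
    the region (flagged ``truncated``) and stacked into non-overlapping
    lanes grouped by sample order; an optional gene track is appended.
    """
    chrom, start_mb, end_mb = region
    if not start_mb < end_mb:
        raise ValueError(f"empty region: start {start_mb} >= end {end_mb} Mb")
    start_bp, end_bp = int(start_mb * 1e6), int(end_mb * 1e6)
    sub = table[(table["chrom"].astype(str) == str(chrom))
                & (table["end"] >= start_bp) & (table["start"] <= end_bp)].copy()
    if len(sub):
        sub["truncated"] = (sub["start"] < start_bp) | (sub["end"] > end_bp)
        sub["start"] = sub["start"].clip(lower=start_bp)
        sub["end"] = sub["end"].clip(upper=end_bp)
        sub = _assign_lanes(sub)
    else:
        sub = sub.assign(truncated=pd.Series(dtype=bool), lane=pd.Series(dtype=int))
    tables = {"intervals": sub.reset_index(drop=True)}
    if genes is not None:
        gsub = genes[(genes["chrom"].astype(str) == str(chrom))
                     & (genes["end"] >= start_bp) & (genes["start"] <= end_bp)]
        tables["genes"] = gsub.reset_index(drop=True)
    return PlotSpec(kind=kind, tables=tables, style={
        "chrom": str(chrom), "start_bp": start_bp, "end_bp": end_bp,
        "cn_colors": dict(DEFAULT_CN_COLORS), **(style or {})})


def prepare_cnvr_map(cnvr: pd.DataFrame, chrom_lengths: dict[str, int],
                     style: dict | None = None) -> PlotSpec:
    """Genome-wide CNVR distribution map: one lane per chromosome,
    regions colored by type."""
    chroms = sorted(chrom_lengths, key=chrom_sort_key)
    lanes = pd.DataFrame({
        "chrom": chroms,
        "lane": range(len(chroms)),
        "length_bp": [chrom_lengths[c] for c in chroms],
    })
    glyphs = cnvr.merge(lanes[["chrom", "lane"]], on="chrom", how="inner")
    return PlotSpec(kind="cnvr_map",
                    tables={"chromosomes": lanes,
                            "glyphs": glyphs.reset_index(drop=True)},
                    style={"type_colors": dict(DEFAULT_CNVR_COLORS),
                           **(style or {})})


def prepare_cnv_summary(summary, style: dict | None = None) -> PlotSpec:
    """Panelized CNV summary (by length group/type, chromosome, state,
    sample) from a :class:`cnvroh.cnv.CnvSummary`."""
    return PlotSpec(kind="cnv_summary", tables={
        "by_length_type": summary.by_length_type,
        "by_chrom_type": summary.by_chrom_type,
        "by_state": summary.by_state,
        "by_sample": summary.by_sample,
    }, style=style or {})


def prepare_snp_density(density: pd.DataFrame,
                        style: dict | None = None) -> PlotSpec:
    return PlotSpec(kind="snp_density", tables={"density": density},
                    style=style or {})


def prepare_roh_frequency(incidence: pd.DataFrame,
                          threshold: float | None = None,
                          style: dict | None = None) -> PlotSpec:
    return PlotSpec(kind="roh_frequency", tables={"incidence": incidence},
                    style={"threshold": threshold, **(style or {})})


def render(spec: PlotSpec, path, dpi: int = 150,
           figsize: tuple[float, float] | None = None) -> None:
    """Draw a prepared spec to ``path`` (format from the extension)."""
    renderers = {
        "cnv_region": _render_region, "roh_region": _render_region,
        "cnvr_map": _render_cnvr_map, "cnv_summary": _render_cnv_summary,
        "snp_density": _render_snp_density, "roh_frequency": _render_roh_freq,
    }
    if spec.kind not in renderers:
        raise ValueError(f"unknown plot kind {spec.kind!r}")
    fig = renderers[spec.kind](spec, figsize)
    fig.savefig(path, dpi=dpi)
    plt.close(fig)


def _render_region(spec: PlotSpec, figsize):
    fig, ax = plt.subplots(figsize=figsize or (10, 4))
    ints = spec.tables["intervals"]
    colors = spec.style.get("cn_colors", DEFAULT_CN_COLORS)
    for row in ints.itertuples():
        if "cn" in ints.columns:
            color = colors.get(int(row.cn), "#999999")
        else:
            color = ROH_COLOR
        ax.barh(row.lane, row.end - row.start + 1, left=row.start,
                height=0.8, color=color)
    genes = spec.tables.get("genes")
    if genes is not None and len(genes):
        gy = -1.5
        for g in genes.itertuples():
            ax.barh(gy, g.end - g.start + 1, left=g.start, height=0.4,
                    color=GENE_COLOR)
            ax.text(g.start, gy - 0.6, g.gene_name, fontsize=7)
    ax.set_xlim(spec.style["start_bp"], spec.style["end_bp"])
    ax.set_xlabel(f"chr{spec.style['chrom']} position (bp)")
    ax.set_ylabel("track")
    return fig


def _render_cnvr_map(spec: PlotSpec, figsize):
    fig, ax = plt.subplots(figsize=figsize or (10, 6))
    lanes = spec.tables["chromosomes"]
    colors = spec.style.get("type_colors", DEFAULT_CNVR_COLORS)
    for row in lanes.itertuples():
        ax.barh(row.lane, row.length_bp, left=0, height=0.25, color="#dddddd")
    for g in spec.tables["glyphs"].itertuples():
        ax.barh(g.lane, g.end - g.start + 1, left=g.start, height=0.6,
                color=colors.get(g.cnvr_type, "#333333"))
    ax.set_yticks(lanes["lane"], lanes["chrom"])
    ax.invert_yaxis()
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("chromosome")
    return fig


def _render_cnv_summary(spec: PlotSpec, figsize):
    fig, axes = plt.subplots(2, 2, figsize=figsize or (11, 8))
    blt = spec.tables["by_length_type"]
    pv = blt.pivot_table(index="length_group", columns="cnv_type",
                         values="count", fill_value=0, observed=False)
    pv.plot.bar(ax=axes[0, 0], stacked=True, legend=True)
    axes[0, 0].set_title("CNVs by length group")
    bct = spec.tables["by_chrom_type"]
    pv2 = bct.pivot_table(index="chrom", columns="cnv_type",
                          values="count", fill_value=0, observed=False)
    pv2.plot.bar(ax=axes[0, 1], stacked=True, legend=False)
    axes[0, 1].set_title("CNVs by chromosome")
    bs = spec.tables["by_state"]
    axes[1, 0].bar(bs["cn"].astype(str), bs["count"])
    axes[1, 0].set_title("CNVs by copy-number state")
    ps = spec.tables["by_sample"]
    axes[1, 1].hist(ps["count"], bins=20)
    axes[1, 1].set_title("CNVs per sample")
    fig.tight_layout()
    return fig


def _render_snp_density(spec: PlotSpec, figsize):
    fig, ax = plt.subplots(figsize=figsize or (8, 4))
    d = spec.tables["density"]
    ax.bar(d["chrom"].astype(str), d["mean_gap_bp"] / 1000.0)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("mean inter-SNP gap (kb)")
    return fig


def _render_roh_freq(spec: PlotSpec, figsize):
    inc = spec.tables["incidence"]
    chroms = inc["chrom"].unique()
    fig, axes = plt.subplots(len(chroms), 1, squeeze=False,
                             figsize=figsize or (10, 1.8 * len(chroms)))
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = inc[inc["chrom"] == chrom]
        ax.plot(sub["pos"], sub["freq"], lw=0.8)
        thr = spec.style.get("threshold")
        if thr is not None:
            ax.axhline(thr, color="red", ls="--", lw=0.8)
        ax.set_ylabel(f"chr{chrom}")
        ax.set_ylim(0, 1)
    axes[-1, 0].set_xlabel("position (bp)")
    fig.tight_layout()
    return fig
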