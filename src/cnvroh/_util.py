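"""Shared helpers: chromosome normalization and ordering, length bins."""

from __future__ import annotations

import numpy as np
import pandas as pd

SEX_CHROMS = frozenset({"X", "Y", "MT"})


def normalize_chrom(chrom) -> str:
    """Strip a leading ``chr`` prefix and canonicalize sex/mito labels.

    ``chrM``/``M`` become ``MT``; case of X/Y is upper-cased; autosome
    labels are returned as their decimal string.
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    cu = c.upper()
    if cu == "M":
        return "MT"
    if cu in SEX_CHROMS:
        return cu
    return c


def is_recognized_chrom(chrom: str) -> bool:
    """Autosome (decimal integer label) or X/Y/MT."""
    return chrom.isdigit() or chrom in SEX_CHROMS


def is_autosome(chrom: str) -> bool:
    return str(chrom).isdigit()


def chrom_sort_key(chrom: str):
    """Numeric order for autosomes, then X, Y, MT, then anything else."""
    c = str(chrom)
    if c.isdigit():
        return (0, int(c), "")
    order = {"X": 0, "Y": 1, "MT": 2}
    if c in order:
        return (1, order[c], "")
    return (2, 0, c)


def sort_by_chrom(df: pd.DataFrame, chrom_col: str = "chrom",
                  extra_cols: list[str] | None = None) -> pd.DataFrame:
    """Sort a frame by chromosome (natural order) then extra columns."""
    key = df[chrom_col].map(chrom_sort_key)
    tmp = df.assign(_ck=key)
    cols = ["_ck"] + (extra_cols or [])
    out = tmp.sort_values(cols, kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)


def length_group_labels(breaks) -> list[str]:
    """Human-readable labels for half-open bins [b_i, b_{i+1})."""

    def fmt(b) -> str:
        if np.isinf(b):
            return "inf"
        b = int(b)
        if b >= 1_000_000 and b % 1_000_000 == 0:
            return f"{b // 1_000_000}Mb"
        if b >= 1_000 and b % 1_000 == 0:
            return f"{b // 1_000}kb"
        return str(b)

    return [f"{fmt(lo)}-{fmt(hi)}" for lo, hi in zip(breaks[:-1], breaks[1:])]


def assign_length_group(lengths, breaks) -> pd.Categorical:
    """Bin lengths into half-open intervals [b_i, b_{i+1}).

    Raises ``ValueError`` on non-increasing breaks.
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks[:-1], breaks[1:])):
        raise ValueError(f"length breaks must be strictly increasing: {breaks}")
    labels = length_group_labels(breaks)
    idx = np.searchsorted(breaks, np.asarray(lengths, dtype=float), side="right") - 1
    idx = np.clip(idx, 0, len(labels) - 1)
    return pd.Categorical.from_codes(idx, categories=labels, ordered=True)
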