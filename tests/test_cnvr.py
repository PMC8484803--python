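"""CNVR calling: sweep merge vs connected-components oracle, typing,
frequency thresholding."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvroh.cnvr import call_cnvr, classify_cnvr, cnvr_summaries, high_freq_cnvr
from conftest import random_intervals


def _cnv(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "cn"])
    df["cnv_type"] = np.where(df["cn"] < 2, "deletion", "duplication")
    df["length"] = df["end"] - df["start"] + 1
    return df


def overlap_components_oracle(cnv: pd.DataFrame) -> set[frozenset]:
    """Connected components of the pairwise >=1 bp closed-interval
    overlap graph (independent of the sweep)."""
    g = nx.Graph()
    g.add_nodes_from(cnv.index)
    for chrom, sub in cnv.groupby("chrom"):
        idx = sub.index.to_numpy()
        s = sub["start"].to_numpy()[:, None]
        e = sub["end"].to_numpy()[:, None]
        ov = (s <= e.T) & (s.T <= e)
        ii, jj = np.nonzero(np.triu(ov, k=1))
        g.add_edges_from(zip(idx[ii], idx[jj]))
    return {frozenset(c) for c in nx.connected_components(g)}


class TestCallCnvr:
    def test_one_shared_bp_merges(self):
        cnv = _cnv([("S1", "1", 100, 200, 1), ("S2", "1", 200, 300, 1)])
        cnvr, member = call_cnvr(cnv)
        assert len(cnvr) == 1
        row = cnvr.iloc[0]
        assert (row["start"], row["end"], row["n_cnv"], row["n_samples"]) == \
            (100, 300, 2, 2)

    def test_bookended_intervals_stay_separate(self):
        cnv = _cnv([("S1", "1", 100, 200, 1), ("S2", "1", 201, 300, 1)])
        cnvr, _ = call_cnvr(cnv)
        assert len(cnvr) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_connected_components_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cnv = random_intervals(rng, 400, with_samples=True)
        cnv["cn"] = rng.choice([0, 1, 3, 4], size=len(cnv))
        cnvr, member = call_cnvr(cnv)
        got = {frozenset(member.index[member == cid]) for cid in cnvr["cnvr_id"]}
        assert got == overlap_components_oracle(cnv)
        # bounds equal the member min/max
        for row in cnvr.itertuples():
            members = cnv.loc[member.index[member == row.cnvr_id]]
            assert row.start == members["start"].min()
            assert row.end == members["end"].max()

    def test_membership_partitions_input(self, clean_cohort_cnv):
        clean, _ = clean_cohort_cnv
        cnvr, member = call_cnvr(clean)
        assert member.notna().all()
        assert cnvr["n_cnv"].sum() == len(clean)

    def test_output_regions_never_overlap(self, clean_cohort_cnv):
        clean, _ = clean_cohort_cnv
        cnvr, _ = call_cnvr(clean)
        for _, sub in cnvr.groupby("chrom"):
            sub = sub.sort_values("start")
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()

    def test_adding_a_cnv_is_monotone(self):
        rng = np.random.default_rng(7)
        cnv = random_intervals(rng, 60, with_samples=True)
        cnv["cn"] = 1
        base, _ = call_cnvr(cnv)
        extra = cnv.iloc[:1].assign(start=1, end=5, sample_id="NEW")
        bigger, _ = call_cnvr(pd.concat([cnv, extra], ignore_index=True))
        assert len(bigger) <= len(base) + 1

    def test_empty_input(self):
        cnvr, member = call_cnvr(pd.DataFrame(
            columns=["sample_id", "chrom", "start", "end", "cn"]))
        assert len(cnvr) == 0 and len(member) == 0


class TestClassify:
    @pytest.mark.parametrize("cns,expected", [
        ([1, 0], "Deletion"),
        ([3, 4], "Duplication"),
        ([1, 3], "Mixed"),
        ([0], "Deletion"),
    ])
    def test_examples(self, cns, expected):
        assert classify_cnvr(cns) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.sampled_from([0, 1, 3, 4, 5]), min_size=1, max_size=10))
    def test_matches_set_enumeration(self, cns):
        has_del = any(c < 2 for c in cns)
        has_dup = any(c > 2 for c in cns)
        expected = ("Mixed" if has_del and has_dup
                    else "Deletion" if has_del else "Duplication")
        assert classify_cnvr(cns) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_cnvr([])


class TestSummariesAndHighFreq:
    def test_per_chromosome_sums(self, clean_cohort_cnv):
        clean, _ = clean_cohort_cnv
        cnvr, _ = call_cnvr(clean)
        brief, per_chrom = cnvr_summaries(cnvr)
        oracle = cnvr.groupby("chrom")["length"].agg(["size", "sum"])
        for row in per_chrom.itertuples():
            assert row.count == oracle.loc[row.chrom, "size"]
            assert row.total_length_bp == oracle.loc[row.chrom, "sum"]
        assert brief["count"].sum() == len(cnvr)

    def test_single_region_per_chrom_table(self):
        cnv = _cnv([("S1", "3", 1, 1_000_000, 1)])
        cnvr, _ = call_cnvr(cnv)
        _, per_chrom = cnvr_summaries(cnvr)
        assert per_chrom.iloc[0].tolist() == ["3", 1, 1_000_000]

    def test_threshold_arithmetic(self):
        cnvr = pd.DataFrame({"cnvr_id": ["CNVR_1_1"], "chrom": ["1"],
                             "start": [1], "end": [10], "length": [10],
                             "n_cnv": [14], "n_samples": [14],
                             "n_del": [14], "n_dup": [0],
                             "cnvr_type": ["Deletion"]})
        kept = high_freq_cnvr(cnvr, sample_size=268, common_cnv_threshold=0.05)
        assert len(kept) == 1 and kept.iloc[0]["freq"] == pytest.approx(14 / 268)

    def test_threshold_one_empties(self):
        cnvr = pd.DataFrame({"cnvr_id": ["x"], "chrom": ["1"], "start": [1],
                             "end": [10], "length": [10], "n_cnv": [5],
                             "n_samples": [5], "n_del": [5], "n_dup": [0],
                             "cnvr_type": ["Deletion"]})
        assert len(high_freq_cnvr(cnvr, sample_size=10,
                                  common_cnv_threshold=1.0)) == 0

    def test_sample_size_consistency_checked(self):
        cnvr = pd.DataFrame({"cnvr_id": ["x"], "chrom": ["1"], "start": [1],
                             "end": [10], "length": [10], "n_cnv": [5],
                             "n_samples": [5], "n_del": [5], "n_dup": [0],
                             "cnvr_type": ["Deletion"]})
        with pytest.raises(ValueError, match="sample_size"):
            high_freq_cnvr(cnvr, sample_size=3)

    def test_planted_region_is_only_common_cnvr(self, cohort, clean_cohort_cnv):
        clean, _ = clean_cohort_cnv
        cnvr, _ = call_cnvr(clean)
        kept = high_freq_cnvr(cnvr, sample_size=cohort["config"]["n_samples"],
                              common_cnv_threshold=0.1)
        planted = cohort["cnv"]["planted_region"]
        assert len(kept) == 1
        assert kept.iloc[0]["chrom"] == planted["chrom"]
        assert kept.iloc[0]["start"] == planted["start"]
        assert kept.iloc[0]["end"] == planted["end"]
        assert kept.iloc[0]["n_samples"] == len(cohort["cnv"]["planted_carriers"])
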