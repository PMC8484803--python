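"""Map matching between assemblies, SNP density, SNP-anchored liftover."""

import numpy as np
import pandas as pd
import pytest

from cnvroh.fixtures import FixtureConfig, gen_maps
from cnvroh.mapconv import (
    MapMismatchError,
    convert_coord,
    convert_map,
    converted_to_target_map,
    snp_density,
)


def _map(rows):
    return pd.DataFrame(rows, columns=["snp_name", "chrom", "pos"])


@pytest.fixture(scope="module")
def perturbed_maps():
    config = FixtureConfig(seed=5)
    rng = np.random.default_rng(config.seed)
    default, target, ledger = gen_maps(config, rng)
    return config, default, target, ledger


class TestConvertMap:
    def test_identical_maps_all_same_chr(self):
        m = _map([("rs1", "1", 100), ("rs2", "2", 500)])
        conv, summary, dens = convert_map(m, m.copy())
        assert (conv["match_class"] == "same_chr").all()
        counts = dict(zip(summary["match_class"], summary["n_snps"]))
        assert counts == {"same_chr": 2, "chr_changed": 0,
                          "missing_in_target": 0, "missing_in_default": 0}

    def test_single_chromosome_move_classified(self):
        d = _map([("rs1", "2", 100), ("rs2", "2", 500)])
        t = _map([("rs1", "2", 100), ("rs2", "5", 900)])
        conv, summary, _ = convert_map(d, t)
        moved = conv[conv["match_class"] == "chr_changed"]
        assert moved["snp_name"].tolist() == ["rs2"]

    def test_planted_perturbation_rates_recovered(self, perturbed_maps):
        config, default, target, ledger = perturbed_maps
        conv, summary, _ = convert_map(default, target)
        counts = dict(zip(summary["match_class"], summary["n_snps"]))
        assert counts["missing_in_target"] == len(ledger["missing_in_target"])
        assert counts["chr_changed"] == len(ledger["chr_changed"])
        assert counts["missing_in_default"] == 0
        missing = set(conv.loc[conv["match_class"] == "missing_in_target",
                               "snp_name"])
        assert missing == set(ledger["missing_in_target"])

    def test_disjoint_maps_rejected(self):
        d = _map([("rs1", "1", 100)])
        t = _map([("rs2", "1", 100)])
        with pytest.raises(MapMismatchError, match="same SNP chip"):
            convert_map(d, t)

    def test_target_map_export_drops_missing(self, perturbed_maps):
        _, default, target, ledger = perturbed_maps
        conv, _, _ = convert_map(default, target)
        out = converted_to_target_map(conv)
        assert len(out) == len(target)
        assert not set(ledger["missing_in_target"]) & set(out["snp_name"])


class TestSnpDensity:
    def test_two_snp_chromosome(self):
        d = snp_density(_map([("a", "1", 1_001), ("b", "1", 2_001)]))
        row = d.iloc[0]
        assert (row["span_bp"], row["mean_gap_bp"]) == (1000, 1000.0)

    def test_single_snp_chromosome_flagged(self):
        d = snp_density(_map([("a", "1", 5)]))
        assert bool(d.iloc[0]["degenerate"])
        assert np.isnan(d.iloc[0]["mean_gap_bp"])

    def test_uniform_fixture_mean_gap(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(np.arange(1, 50_000_001), size=10_000,
                                 replace=False))
        m = _map([(f"s{i}", "1", int(p)) for i, p in enumerate(pos)])
        d = snp_density(m)
        assert d.iloc[0]["mean_gap_bp"] == pytest.approx(50e6 / 9999, rel=0.01)


class TestConvertCoord:
    def _intervals(self, map_df, rng, n=50):
        rows = []
        for i in range(n):
            chrom = str(rng.integers(1, 6))
            s = int(rng.integers(1, 45_000_000))
            rows.append({"interval_id": f"I{i}", "chrom": chrom,
                         "start": s, "end": s + int(rng.integers(50_000, 2_000_000))})
        return pd.DataFrame(rows)

    def test_identity_liftover(self, perturbed_maps):
        _, default, _, _ = perturbed_maps
        conv, _, _ = convert_map(default, default.copy())
        rng = np.random.default_rng(1)
        ints = self._intervals(default, rng)
        res, summary = convert_coord(ints, conv)
        ok = res[res["converted"]]
        assert summary.n_converted + summary.n_failed == len(ints)
        assert (ok["length_delta"] == 0).all()
        assert not ok["order_inverted"].any()
        # converted span is exactly the span of the interval's own markers
        for row in ok.itertuples():
            snps = default[(default["chrom"] == row.chrom)
                           & (default["pos"] >= row.start)
                           & (default["pos"] <= row.end)]
            assert row.start_target == snps["pos"].min()
            assert row.end_target == snps["pos"].max()

    def test_empty_interval_fails_cleanly(self):
        m = _map([("rs1", "1", 1_000)])
        conv, _, _ = convert_map(m, m.copy())
        res, summary = convert_coord(pd.DataFrame(
            [{"interval_id": "I0", "chrom": "1", "start": 5_000, "end": 6_000}]),
            conv)
        assert not res.iloc[0]["converted"]
        assert res.iloc[0]["failure_reason"] == "no_snps_in_interval"
        assert summary.failures_by_reason == {"no_snps_in_interval": 1}

    def test_uniform_shift_oracle(self):
        config = FixtureConfig(seed=5, map_missing_rate=0, map_chr_change_rate=0,
                               map_shift_rate=0, map_uniform_shift_bp=10_000)
        rng = np.random.default_rng(config.seed)
        default, target, ledger = gen_maps(config, rng)
        assert ledger["uniform_shift_bp"] == 10_000
        ints = self._intervals(default, np.random.default_rng(2))
        conv_id, _, _ = convert_map(default, default.copy())
        res_id, _ = convert_coord(ints, conv_id)
        conv_sh, _, _ = convert_map(default, target)
        res_sh, _ = convert_coord(ints, conv_sh)
        ok_sh = res_sh[res_sh["converted"]].set_index("interval_id")
        ok_id = res_id[res_id["converted"]].set_index("interval_id")
        assert list(ok_sh.index) == list(ok_id.index)
        assert (ok_sh["length_delta"] == 0).all()
        assert ((ok_sh["start_target"] - ok_id["start_target"]) == 10_000).all()

    def test_split_chromosome_failure_and_tolerance(self):
        d = _map([(f"rs{i}", "1", 100 * (i + 1)) for i in range(10)])
        t = d.copy()
        t.loc[:4, "chrom"] = "7"     # 5 of 10 markers move away
        conv, _, _ = convert_map(d, t)
        ints = pd.DataFrame([{"interval_id": "I0", "chrom": "1",
                              "start": 1, "end": 2_000}])
        res, _ = convert_coord(ints, conv, minority_tolerance=0.1)
        assert res.iloc[0]["failure_reason"] == "snps_split_across_chromosomes"
        res2, _ = convert_coord(ints, conv, minority_tolerance=0.6)
        assert res2.iloc[0]["converted"]
        # tie at 5/5: modal chromosome prefers the default one
        assert res2.iloc[0]["chrom_target"] == "1"

    def test_order_inversion_detected(self):
        d = _map([("rs1", "1", 100), ("rs2", "1", 200), ("rs3", "1", 300)])
        t = _map([("rs1", "1", 100), ("rs2", "1", 400), ("rs3", "1", 300)])
        conv, _, _ = convert_map(d, t)
        res, _ = convert_coord(pd.DataFrame(
            [{"interval_id": "I0", "chrom": "1", "start": 50, "end": 350}]), conv)
        assert bool(res.iloc[0]["order_inverted"])

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError, match="convert_map"):
            convert_coord(pd.DataFrame(), pd.DataFrame())
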