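import numpy as np
import pandas as pd
import pytest

from cnvroh import formats_io
from cnvroh.fixtures import FixtureConfig, gen_cohort


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """Default synthetic cohort (seed 42) plus its truth ledger."""
    outdir = tmp_path_factory.mktemp("cohort")
    ledger = gen_cohort(FixtureConfig(seed=42), outdir)
    return ledger


@pytest.fixture(scope="session")
def clean_cohort_cnv(cohort):
    from cnvroh.cnv import clean_cnv

    parsed = formats_io.read_cnv(cohort["files"]["penncnv"], "penncnv")
    clean, report = clean_cnv(parsed.records)
    return clean, report


@pytest.fixture(scope="session")
def cohort_roh(cohort):
    return formats_io.read_plink_hom(cohort["files"]["hom"])


@pytest.fixture(scope="session")
def cohort_map(cohort):
    map_df, _ = formats_io.read_snp_map(cohort["files"]["map_default"])
    return map_df


def random_intervals(rng, n, n_chrom=5, chrom_len=10_000_000,
                     max_len=500_000, with_samples=False):
    """Random closed intervals for oracle comparisons."""
    chroms = rng.integers(1, n_chrom + 1, size=n).astype(str)
    starts = rng.integers(1, chrom_len, size=n)
    lengths = rng.integers(1, max_len, size=n)
    df = pd.DataFrame({
        "chrom": chroms, "start": starts,
        "end": np.minimum(starts + lengths - 1, chrom_len),
    })
    if with_samples:
        df["sample_id"] = [f"S{int(i)}" for i in rng.integers(0, 20, size=n)]
    return df
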