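import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from transmr import SummaryStats, TraitMeta

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_sumstats(rows, trait="bmi", trait_type="quantitative", pop="EAS",
                  sd=1.0):
    """Build a SummaryStats from (snp, chrom, pos, ea, oa, eaf, beta, se, n)
    tuples; P recomputed from z."""
    from scipy import stats as sps

    df = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ea", "oa",
                                     "eaf", "beta", "se", "n"])
    df["p"] = 2 * sps.norm.sf(np.abs(df["beta"] / df["se"]))
    df = df[["snp", "chrom", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]]
    kw = dict(sd_native=sd) if trait_type == "quantitative" else \
        dict(n_cases=10_000, n_controls=10_000)
    return SummaryStats(meta=TraitMeta(trait, trait_type, population=pop, **kw),
                        table=df)


@pytest.fixture
def toy_exposure():
    return make_sumstats([
        ("rs1", "1", 1000, "A", "G", 0.30, 0.10, 0.010, 100_000),
        ("rs2", "1", 2000, "C", "T", 0.40, -0.08, 0.012, 100_000),
        ("rs3", "2", 5000, "G", "A", 0.20, 0.12, 0.015, 100_000),
        ("rs4", "2", 9000, "T", "C", 0.50, 0.06, 0.011, 100_000),
    ])


@pytest.fixture
def toy_outcome():
    return make_sumstats([
        ("rs1", "1", 1000, "A", "G", 0.31, 0.050, 0.020, 150_000),
        ("rs2", "1", 2000, "T", "C", 0.61, 0.041, 0.022, 150_000),  # flipped
        ("rs3", "2", 5000, "G", "A", 0.19, 0.060, 0.025, 150_000),
        ("rs4", "2", 9000, "T", "C", 0.52, 0.030, 0.021, 150_000),
    ], trait="cad", trait_type="binary")
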