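"""Shared fixtures: hand-built sumstats tables and a small simulated study."""
import numpy as np
import pandas as pd
import pytest

try:
    from hypothesis import settings
    settings.register_profile("suite", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:  # pragma: no cover - hypothesis is optional
    pass

from genomicpca.sim import SimConfig, make_study
from genomicpca.sumstats import SumStatsTable


def build_table(trait="t", snps=None, a1=None, a2=None, eaf=None, beta=None,
                se=None, z=None, n=None, chrom=None, bp=None) -> SumStatsTable:
    """Construct a SumStatsTable from short parallel lists."""
    m = len(snps)
    beta = [np.nan] * m if beta is None else beta
    se = [np.nan] * m if se is None else se
    if z is None:
        z = [b / s for b, s in zip(beta, se)]
    df = pd.DataFrame({
        "snp": snps,
        "chrom": chrom or ["1"] * m,
        "bp": bp or list(range(1, m + 1)),
        "a1": a1, "a2": a2, "eaf": eaf,
        "beta": beta, "se": se, "z": z,
        "n": n or [10_000] * m,
    })
    return SumStatsTable(trait, df)


@pytest.fixture()
def four_variant_table():
    return build_table(
        trait="vol1",
        snps=["rs1", "rs2", "rs3", "rs4"],
        a1=["A", "C", "G", "T"], a2=["G", "T", "A", "C"],
        eaf=[0.3, 0.5, 0.1, 0.45],
        beta=[0.10, -0.05, 0.0, 0.02], se=[0.05, 0.02, 0.1, 0.01])


@pytest.fixture(scope="session")
def small_study():
    """A 4-trait full-overlap study, large enough for LDSC to behave."""
    cfg = SimConfig(k=4, n_ind=2_500, n_snp=6_000, block_size=10,
                    lambda_g=0.8, h2=0.35, overlap="full", seed=11)
    return make_study(cfg)
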