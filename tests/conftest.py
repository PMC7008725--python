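import numpy as np
import pandas as pd
import pytest

from pleiocca import CausalGene, SimConfig, SummaryStats
from pleiocca.sumstats import REQUIRED_COLUMNS


def make_study(
    disease: str,
    snps: list[tuple],
    n: int = 1000,
) -> SummaryStats:
    """Build a SummaryStats from (snp, chrom, pos, a1, a2, beta, se) tuples."""
    rows = []
    for snp, chrom, pos, a1, a2, beta, se in snps:
        from scipy import stats

        p = 2 * stats.norm.sf(abs(beta / se))
        rows.append((snp, chrom, pos, a1, a2, beta, se, max(p, 1e-300), n))
    return SummaryStats(
        disease=disease,
        table=pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)),
        n=n,
    )


@pytest.fixture
def two_studies():
    s1 = make_study(
        "d1",
        [
            ("rs1", "1", 100, "A", "G", 0.10, 0.05),
            ("rs2", "1", 200, "C", "T", -0.05, 0.02),
            ("rs3", "2", 150, "G", "C", 0.02, 0.01),
        ],
    )
    s2 = make_study(
        "d2",
        [
            ("rs1", "1", 100, "G", "A", 0.10, 0.04),  # swapped orientation
            ("rs2", "1", 200, "C", "T", 0.07, 0.03),
            ("rs3", "2", 150, "G", "C", -0.01, 0.02),
        ],
        n=2000,
    )
    return [s1, s2]


@pytest.fixture(scope="session")
def small_sim():
    return SimConfig(
        seed=7,
        n_reference=300,
        n_cohorts=(1500, 1500, 1500),
        n_snps=80,
        n_genes=10,
        block_rho=0.5,
        causal_genes=[CausalGene(gene_index=3, traits=(0, 1), effect=0.08)],
    )


@pytest.fixture(scope="session")
def null_sim():
    return SimConfig(
        seed=13,
        n_reference=300,
        n_cohorts=(1200, 1200, 1200),
        n_snps=60,
        n_genes=12,
        block_rho=0.3,
    )
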