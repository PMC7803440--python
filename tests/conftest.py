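from __future__ import annotations

import numpy as np
import pytest

from mrbp import SummaryStatRecord, SyntheticStudyConfig, generate_summary_pair


def make_record(
    variant_id="rs1",
    chromosome="1",
    position=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-9,
    n=100_000,
    trait="SBP",
) -> SummaryStatRecord:
    return SummaryStatRecord(
        variant_id=variant_id,
        chromosome=chromosome,
        position=position,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
        trait=trait,
    )


def random_effect_arrays(rng: np.random.Generator, j: int):
    """A random instrument set as (bx, sx, by, sy) arrays."""
    bx = rng.normal(0.0, 0.05, j)
    bx[np.abs(bx) < 1e-3] = 1e-3  # keep ratios well defined
    sx = rng.uniform(0.001, 0.01, j)
    by = rng.normal(0.0, 0.02, j)
    sy = rng.uniform(0.002, 0.05, j)
    return bx, sx, by, sy


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_study():
    """One deterministic simulated exposure/outcome pair (50 SNPs)."""
    return generate_summary_pair(SyntheticStudyConfig(n_snps=50, seed=7))
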