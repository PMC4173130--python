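"""Shared synthetic fixtures: one European-like 800 kb study region.

Session-scoped so the expensive panel and map are built once; tests that
need different conditions build their own.
"""

import numpy as np
import pytest

import malecotmap as mm

# study-region conditions used throughout: ~100 SNPs over 800 kb, 10 LDU
# total with 12 LD blocks and 15% diffuse background recombination
REGION = dict(n_snps=100, region_kb=800.0, n_blocks=12, step_ldu_total=10.0,
              background_fraction=0.15)


@pytest.fixture(scope="session")
def profile():
    return mm.simulate_recombination_profile(seed=11, **REGION)


@pytest.fixture(scope="session")
def panel(profile):
    return mm.simulate_haplotypes(profile, n_haplotypes=4000, maf_min=0.05, seed=12)


@pytest.fixture(scope="session")
def ref_map(panel):
    """LDU map fitted from a reference panel (separate individuals)."""
    ref = mm.pair_haplotypes(panel, 1000, seed=13)
    pairs = mm.pairwise_ld_table(ref)
    return mm.fit_ldu_map(pairs, ref.positions_kb, snp_ids=ref.snp_ids)


@pytest.fixture(scope="session")
def cohort(panel):
    """500-individual genotype cohort drawn from the same panel."""
    return mm.pair_haplotypes(panel, 500, seed=14)
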