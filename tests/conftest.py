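import numpy as np
import pandas as pd
import pytest

import cnaloss as cl


@pytest.fixture(scope="session")
def genome_small():
    """3 x 40 Mb genome, 10 kb SNP spacing, 300 genes."""
    return cl.make_genome(seed=1, chrom_sizes=[40_000_000] * 3,
                          snp_spacing=10_000, n_genes=300)


@pytest.fixture(scope="session")
def genome_dense():
    """Platform-faithful density (1 SNP / 3.3 kb) for recovery tests."""
    return cl.make_genome(seed=1, chrom_sizes=[40_000_000] * 3,
                          snp_spacing=3_300, n_genes=300)


@pytest.fixture(scope="session")
def sets_small(genome_small):
    return cl.make_gene_sets(genome_small, stop_size=30, cyclops_size=10,
                             seed=2)


@pytest.fixture(scope="session")
def sets_dense(genome_dense):
    return cl.make_gene_sets(genome_dense, stop_size=30, cyclops_size=10,
                             seed=2)


def diploid_profile(genome, sample_id="D", rho=1.0):
    """All-(1,1) truth profile."""
    segs = pd.DataFrame(
        [(c, 0, s, 1, 1) for c, s in genome.chromosomes],
        columns=["chrom", "start", "end", "nA", "nB"])
    return cl.TruthProfile(sample_id=sample_id, rho=rho, segments=segs)


def single_state_profile(genome, nA, nB, sample_id="S", rho=1.0):
    segs = pd.DataFrame(
        [(c, 0, s, nA, nB) for c, s in genome.chromosomes],
        columns=["chrom", "start", "end", "nA", "nB"])
    return cl.TruthProfile(sample_id=sample_id, rho=rho, segments=segs)


def truth_cohort_dict(cohort):
    """sample -> (segments, psi) mapping for calls-level functions."""
    return {t.sample_id: (t.segments, t.psi_true) for t in cohort}
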