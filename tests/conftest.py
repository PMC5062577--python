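import numpy as np
import pytest

from koassoc.io_formats import GeneModel, Transcript
from koassoc.synthdata import SyntheticCohortConfig, generate_cohort


@pytest.fixture
def two_exon_gene():
    """A hand-built plus-strand gene: two 9-bp exons, CDS over both, with a
    known codon layout ATG CAG AAA TTT GGG TAA."""
    t = Transcript("t1", [(100, 109), (200, 209)], 100, 209)
    gene = GeneModel("G", "1", "+", [t])
    cds = {"t1": "ATGCAGAAATTTGGGTAA"}
    return gene, cds


@pytest.fixture
def mirrored_gene():
    """The same locus reflected around coordinate 300 onto the minus strand;
    classifications must be identical for mirrored variants."""
    t = Transcript("t1", [(300 - 209, 300 - 200), (300 - 109, 300 - 100)],
                   300 - 209, 300 - 100)
    gene = GeneModel("G", "1", "-", [t])
    cds = {"t1": "ATGCAGAAATTTGGGTAA"}
    return gene, cds


@pytest.fixture(scope="session")
def small_cohort():
    """A modest two-stratum cohort with one planted effect gene, one
    forced-cis gene and one X-linked gene, reused across tests."""
    cfg = SyntheticCohortConfig(
        n_samples=800, strata={"EA": 0.6, "AA": 0.4}, n_genes=12,
        lof_sites_per_gene=3, maf_range=(0.01, 0.045),
        effects={"G0001": 2.0}, force_cis_genes=("G0002",),
        n_x_genes=2, seed=42)
    return generate_cohort(cfg)
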