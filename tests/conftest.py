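"""Shared fixtures: tiny references, gene models, and a small cohort."""

from __future__ import annotations

import numpy as np
import pytest

from consomatic.simulate import SimConfig, simulate_cohort
from consomatic.variants import GeneModel, ReferenceGenome


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def flat_ref():
    """60 bp single-contig reference with a known sequence."""
    #         1         2         3         4         5         6
    # 123456789012345678901234567890123456789012345678901234567890
    seq = "ATGACGTTACGCAGAGAGAGCTTTGCACGATGCATGGATCCGTAACGCGTACGATTGACA"
    return ReferenceGenome({"chr1": seq})


@pytest.fixture()
def one_gene():
    """Two-exon plus-strand gene on flat_ref: CDS spans both exons (24 bp)."""
    return GeneModel(
        gene_id="geneA",
        chrom="chr1",
        strand="+",
        exons=((1, 12), (31, 42)),
        cds_start=1,
        cds_end=42,
    )


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced cohort (2+2+2 pairs) that still exercises every stage."""
    return SimConfig(
        seed=11,
        n_contigs=1,
        contig_length=150_000,
        n_genes=80,
        n_pairs={"benign": 2, "borderline": 2, "carcinoma": 2},
        germline_snp_rate=3e-4,
    )


@pytest.fixture(scope="session")
def small_cohort(small_sim_config):
    return simulate_cohort(small_sim_config)


@pytest.fixture(scope="session")
def small_cohort_dir(small_cohort, tmp_path_factory):
    from consomatic.simulate import write_cohort

    path = tmp_path_factory.mktemp("cohort")
    write_cohort(small_cohort, path)
    return path
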