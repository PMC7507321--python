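import numpy as np
import pytest

from circnigra import (
    GenomeConfig, GenomeModel, GeneModel, build_editing_model, build_genome,
    default_cohort_design, simulate_cohort,
)
from circnigra._seq import decode


@pytest.fixture(scope="session")
def demo_genome():
    return build_genome(GenomeConfig(), seed=11)


@pytest.fixture(scope="session")
def demo_editing(demo_genome):
    return build_editing_model(demo_genome, seed=12)


@pytest.fixture(scope="session")
def demo_cohort(demo_genome, demo_editing):
    design = default_cohort_design(n_per_group=2, seed=13, sample_sigma=0.2)
    return simulate_cohort(demo_genome, design, editing=demo_editing,
                           n_reads=5000, error_rate=0.0)


@pytest.fixture(scope="session")
def toy_circle_genome():
    """A handcrafted single-chromosome genome with one plus-strand gene whose
    middle exon [300, 400) is circularizable and canonically flanked."""
    rng = np.random.default_rng(99)
    seq = list(decode(rng.integers(0, 4, size=1200).astype(np.uint8)))
    gene = GeneModel(
        gene_id="toy1", chrom="c1", strand="+",
        exons=[(100, 260), (300, 400), (450, 620)],
        circ_exon_index=1, base_expression=1.0, circ_fraction=0.5,
    )
    for s, e in gene.exons:
        seq[e:e + 2] = list("GT")
        seq[s - 2:s] = list("AG")
    genome = GenomeModel(chromosomes={"c1": "".join(seq)}, genes=[gene],
                         alus=[])
    genome.validate()
    return genome
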