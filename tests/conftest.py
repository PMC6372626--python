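import numpy as np
import pytest

from ubcgenomics import synthetic
from ubcgenomics.types import CoverageMask, Genome, GenomeLayout


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """One 200 kb uniform-random chromosome, fixed seed."""
    cfg = synthetic.SimulationConfig(seed=42, n_samples=0, chrom_lengths={"chr1": 200_000})
    genome, _ = synthetic.simulate_reference(cfg)
    return genome


@pytest.fixture(scope="session")
def small_layout(small_genome) -> GenomeLayout:
    return small_genome.layout


@pytest.fixture(scope="session")
def full_mask(small_layout) -> CoverageMask:
    return CoverageMask.full(small_layout)


@pytest.fixture(scope="session")
def three_signatures():
    """Three sparse signatures with low pairwise cosine similarity."""
    ref = synthetic.synthetic_signatures(3, seed=11)
    W = ref.to_numpy()
    for i in range(3):
        for j in range(i + 1, 3):
            cos = W[:, i] @ W[:, j] / np.linalg.norm(W[:, i]) / np.linalg.norm(W[:, j])
            assert cos < 0.6
    return ref


@pytest.fixture(scope="session")
def demo_cohort():
    """A 12-sample end-to-end cohort with hotspot, kataegis, and BFB truth."""
    cfg = synthetic.default_cohort_config(seed=2024, n_samples=12)
    return synthetic.simulate_cohort(cfg)
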