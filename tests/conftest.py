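import numpy as np
import pytest

from myosplice.annotation import GeneModel
from myosplice.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic study shared by read-only tests."""
    return simulate_dataset(SimulationConfig(n_genes=120, seed=11))


def random_toy_gene(rng) -> GeneModel | None:
    """A random gene with <= 4 transcripts drawn from a pool of exon
    variants on a shared scaffold (boundary-shifted, merged and skipped
    forms), or None if the draw violates exon geometry."""
    base = [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900), (1000, 1100)]
    pool = list(base) + [
        (0, 150), (180, 300), (400, 560), (570, 700),  # shifted splice sites
        (200, 500), (600, 900),  # retained introns
    ]
    txs = []
    for _ in range(int(rng.integers(2, 5))):
        k = int(rng.integers(1, 6))
        chosen = sorted(
            {tuple(pool[i]) for i in rng.choice(len(pool), size=k, replace=False)}
        )
        if any(a[1] >= b[0] for a, b in zip(chosen, chosen[1:])):
            continue  # overlapping/touching exons within a transcript
        txs.append(tuple(chosen))
    txs = tuple(dict.fromkeys(txs))
    if not txs:
        return None
    strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel("toy", "1", strand, txs)
    gene.validate()
    return gene


@pytest.fixture
def toy_gene_factory():
    return random_toy_gene
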