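import numpy as np
import pytest

from plastome_hotspots.seqio import Alignment, AnnotatedPlastome, Feature, SequenceRecord
from plastome_hotspots.synthetic_data import make_benchmark


@pytest.fixture(scope="session")
def benchmark_fixture():
    """One deterministic default benchmark shared across tests."""
    return make_benchmark(seed=1)


@pytest.fixture
def tiny_alignment():
    return Alignment(["a", "b", "c", "d"], ["AAG", "AAG", "GAG", "GAA"])


@pytest.fixture
def toy_plastome():
    # 60 bp circular genome with two plus-strand genes and a 10 bp spacer
    seq = "ATGAAACCCGGGTTTAAACCCGGGTTTAAATAGATGCCCAAATTTGGGCCCAAATTTTAG"
    features = [
        Feature("geneA", "PCG", 0, 20, "+"),
        Feature("geneB", "PCG", 30, 50, "+"),
    ]
    return AnnotatedPlastome(SequenceRecord("px", seq, circular=True), features)


def random_alignment(rng, n_taxa, length, gap_frac=0.1, amb_frac=0.05):
    """Random gapped/ambiguous alignment for oracle comparisons."""
    bases = np.array(list("ACGT"))
    mat = bases[rng.integers(0, 4, size=(n_taxa, length))]
    gaps = rng.random((n_taxa, length)) < gap_frac
    mat[gaps] = "-"
    ambs = rng.random((n_taxa, length)) < amb_frac
    mat[ambs] = "N"
    return Alignment(
        [f"t{i}" for i in range(n_taxa)], ["".join(row) for row in mat]
    )
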