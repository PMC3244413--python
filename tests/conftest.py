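import numpy as np
import pytest

from sialoseq.simulate import generate_families, simulate_reads_454


@pytest.fixture(scope="session")
def small_truth():
    """Three families x three copies at 10% divergence, half secreted."""
    return generate_families(3, 3, 0.10, 300, 0.5, seed=7)


@pytest.fixture(scope="session")
def clean_single_transcript_reads():
    """Error-free depth-20 reads from one 600 nt transcript."""
    truth = generate_families(1, 1, 0.0, 600, 0.0, seed=5)
    reads = simulate_reads_454(truth, 344, 20.0, 0.0, 0.0, 0.0, seed=6)
    return truth, reads


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_protein(rng: np.random.Generator, n: int) -> str:
    aa = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(aa[i] for i in rng.integers(0, 20, size=n))
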