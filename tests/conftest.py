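import numpy as np
import pytest

from cyanokit.genome_io import Contig, GenomeRecord


@pytest.fixture
def make_genome():
    """Factory: build a GenomeRecord from raw sequences (auto-named contigs)."""

    def _make(*seqs: str) -> GenomeRecord:
        return GenomeRecord([Contig(f"c{i + 1}", s) for i, s in enumerate(seqs)])

    return _make


@pytest.fixture
def random_dna():
    """Factory: uniform random DNA of a given length from a seeded generator."""

    def _make(n: int, seed: int = 0, gc: float = 0.5) -> str:
        rng = np.random.default_rng(seed)
        probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=n, p=probs))

    return _make
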