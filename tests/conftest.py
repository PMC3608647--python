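import numpy as np
import pytest

from rnaseq_snp_eval import SimConfig, simulate_all
from rnaseq_snp_eval.model import AlignedRead, SequenceRead


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        seed=7,
        n_contigs=2,
        contig_length=30_000,
        n_genes=10,
        n_reads=3_000,
        error_rate=0.002,
        pcr_duplicate_rate=0.1,
        mask_fraction=0.05,
        evidence_depth=5,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    """(ref, truth, rna, evidence, mask, catalog) for a small seeded run."""
    return simulate_all(small_config)


def random_aligned_reads(rng: np.random.Generator, n: int, read_length: int = 10,
                         contigs=("chr1", "chr2"), span: int = 500) -> list[AlignedRead]:
    """Random ungapped alignments; collisions in (contig,start,end,strand) are likely."""
    reads = []
    for i in range(n):
        contig = contigs[rng.integers(len(contigs))]
        start = int(rng.integers(1, span))
        bases = "".join(rng.choice(list("ACGT"), size=read_length))
        quals = "".join(chr(33 + int(q)) for q in rng.integers(10, 40, size=read_length))
        reads.append(
            AlignedRead(
                read_id=f"r{i}",
                contig=contig,
                start=start,
                end=start + read_length - 1,
                strand="+" if rng.random() < 0.5 else "-",
                bases=bases,
                quals=quals,
            )
        )
    return reads


def random_sequence_reads(rng: np.random.Generator, n: int, length: int = 8) -> list[SequenceRead]:
    """Short alphabet-limited reads so exact-string collisions are common."""
    reads = []
    for i in range(n):
        bases = "".join(rng.choice(list("AC"), size=length))
        reads.append(SequenceRead(f"s{i}", bases, "I" * length))
    return reads
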