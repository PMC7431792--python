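"""Shared fixtures: designed single-ORF genomes, a small synthetic phage
pair, and helpers to excise reads from coding regions."""

import numpy as np
import pytest

from virecruit.seqio import GenomeRecord, ReadRecord
from virecruit.orfcall import OrfConfig, call_orfs, proteome
from virecruit.simdata import diverge_genome, random_coding_genome

# stop-rich, start-free spacer: TAA repeats carry stops in frame and no
# ATG/GTG/TTG on either strand
SPACER = "TAA" * 10


@pytest.fixture(scope="session")
def single_orf_genome() -> GenomeRecord:
    """120-nt ORF (ATG + 38 Ala codons + TAA) embedded in stop-rich
    context; exactly one ORF above the 100-nt default threshold."""
    cds = "ATG" + "GCT" * 38 + "TAA"
    assert len(cds) == 120
    return GenomeRecord("g1", SPACER + cds + SPACER)


@pytest.fixture(scope="session")
def small_phage() -> GenomeRecord:
    """A gene-dense ~6 kb circular genome with known random content."""
    return random_coding_genome(6000, seed=7, genome_id="phageA")


@pytest.fixture(scope="session")
def small_phage_orfs(small_phage):
    return [o for o in call_orfs(small_phage) if len(o.protein) >= 60]


@pytest.fixture(scope="session")
def small_decoy(small_phage, small_phage_orfs) -> GenomeRecord:
    """A 60%-proteome-identity relative of the small phage."""
    return diverge_genome(small_phage, small_phage_orfs, 60.0, seed=8,
                          genome_id="decoyA")


def excise_reads(genome: GenomeRecord, orfs, read_len=150, n_per_orf=2,
                 metagenome="m1", seed=0):
    """Reads copied verbatim from coding regions of a genome."""
    rng = np.random.default_rng(seed)
    reads = []
    k = 0
    for orf in orfs:
        span = orf.interval.end - orf.interval.start + 1
        if span <= read_len or orf.interval.end > len(genome.seq):
            continue
        for _ in range(n_per_orf):
            off = int(rng.integers(0, span - read_len + 1))
            start = orf.interval.start - 1 + off
            reads.append(
                ReadRecord(f"ex{k:04d}", genome.seq[start : start + read_len],
                           metagenome)
            )
            k += 1
    return reads


@pytest.fixture(scope="session")
def coding_reads(small_phage, small_phage_orfs):
    return excise_reads(small_phage, small_phage_orfs)
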