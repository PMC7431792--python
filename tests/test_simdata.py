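"""Synthetic community generator: determinism, divergence control, and
sampling statistics."""

import numpy as np
import pandas as pd
import pytest

from virecruit.seqio import GenomeRecord
from virecruit.orfcall import call_orfs, translate_orf
from virecruit.simdata import (
    Community,
    CommunityConfig,
    _nonoverlapping,
    diverge_genome,
    random_coding_genome,
    recovery_harness,
    sample_reads,
)
from virecruit.talign import local_align


@pytest.fixture(scope="module")
def fixture_genome():
    return random_coding_genome(20_000, seed=21, genome_id="fix")


@pytest.fixture(scope="module")
def fixture_orfs(fixture_genome):
    return [o for o in call_orfs(fixture_genome) if len(o.protein) >= 60]


class TestRandomGenome:
    def test_reaches_target_length_and_is_gene_dense(self, fixture_genome, fixture_orfs):
        assert len(fixture_genome.seq) >= 20_000
        coding = sum(o.span_nt() for o in fixture_orfs)
        assert coding / len(fixture_genome.seq) > 0.5

    def test_deterministic(self):
        a = random_coding_genome(3000, seed=5)
        b = random_coding_genome(3000, seed=5)
        assert a.seq == b.seq
        assert a.seq != random_coding_genome(3000, seed=6).seq


class TestDiverge:
    def test_target_100_returns_genome_unchanged(self, fixture_genome, fixture_orfs):
        out = diverge_genome(fixture_genome, fixture_orfs, 100.0, seed=1)
        assert out.seq == fixture_genome.seq

    def test_target_85_measured_identity_in_band(self, fixture_genome, fixture_orfs):
        div = diverge_genome(fixture_genome, fixture_orfs, 85.0, seed=2)
        idents, weights = [], []
        # identity is controlled over the disjoint ORF set the divergence
        # operates on (overlapping spurious calls share mutated bases)
        for orf in _nonoverlapping(fixture_orfs, len(fixture_genome.seq)):
            new = translate_orf(div, orf.interval)
            aln = local_align(orf.protein, new)
            idents.append(aln.pct_identity)
            weights.append(len(orf.protein))
        mean_ident = np.average(idents, weights=weights)
        assert 83.0 <= mean_ident <= 87.0

    def test_same_seed_identical_output(self, fixture_genome, fixture_orfs):
        a = diverge_genome(fixture_genome, fixture_orfs, 90.0, seed=3)
        b = diverge_genome(fixture_genome, fixture_orfs, 90.0, seed=3)
        assert a.seq == b.seq

    def test_orf_coordinates_preserved(self, fixture_genome, fixture_orfs):
        div = diverge_genome(fixture_genome, fixture_orfs, 85.0, seed=4)
        assert len(div.seq) == len(fixture_genome.seq)
        for orf in _nonoverlapping(fixture_orfs, len(fixture_genome.seq)):
            # start/stop codons intact, no internal stop: translation works
            prot = translate_orf(div, orf.interval)
            assert len(prot) == len(orf.protein)

    def test_unreachable_target_rejected(self, fixture_genome, fixture_orfs):
        with pytest.raises(ValueError):
            diverge_genome(fixture_genome, fixture_orfs, 40.0, seed=5)


def _cfg(genomes, weights, n_reads, **kw):
    return CommunityConfig(
        genomes=tuple(genomes), weights=tuple(weights), n_reads=n_reads, **kw
    )


class TestSampleReads:
    def test_zero_reads(self, fixture_genome):
        reads, truth = sample_reads(_cfg([fixture_genome], [1.0], 0))
        assert reads == [] and len(truth) == 0

    def test_weight_one_sends_all_nonbackground_to_genome_one(self, fixture_genome):
        other = random_coding_genome(20_000, seed=22, genome_id="other")
        reads, truth = sample_reads(
            _cfg([fixture_genome, other], [1.0, 0.0], 300,
                 background_fraction=0.3, seed=9)
        )
        origins = set(truth["origin"])
        assert origins <= {"fix", "background"}
        assert "fix" in origins

    def test_read_length_and_truth_size_invariants(self, fixture_genome):
        cfg = _cfg([fixture_genome], [1.0], 250, read_len=120, seed=1)
        reads, truth = sample_reads(cfg)
        assert len(reads) == len(truth) == 250
        assert all(len(r.seq) == 120 for r in reads)
        assert list(truth["read_id"]) == [r.id for r in reads]

    def test_deterministic_given_seed(self, fixture_genome):
        cfg = _cfg([fixture_genome], [1.0], 50, seed=13)
        r1, t1 = sample_reads(cfg)
        r2, t2 = sample_reads(cfg)
        assert r1 == r2
        pd.testing.assert_frame_equal(t1, t2)

    def test_origin_fractions_match_weights(self, fixture_genome):
        other = random_coding_genome(20_000, seed=23, genome_id="g2")
        n = 10_000
        reads, truth = sample_reads(
            _cfg([fixture_genome, other], [0.7, 0.3], n,
                 background_fraction=0.0, error_rate=0.0, seed=2)
        )
        frac = (truth["origin"] == "fix").mean()
        sd = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) < 3 * sd

    def test_error_free_reads_match_genome(self, fixture_genome):
        reads, truth = sample_reads(
            _cfg([fixture_genome], [1.0], 30, error_rate=0.0,
                 background_fraction=0.0, seed=3)
        )
        doubled = fixture_genome.seq + fixture_genome.seq
        from virecruit.seqio import reverse_complement

        for r, row in zip(reads, truth.itertuples()):
            raw = doubled[row.position - 1 : row.position - 1 + len(r.seq)]
            expect = raw if row.strand == "+" else reverse_complement(raw)
            assert r.seq == expect

    def test_read_longer_than_genome_rejected(self):
        tiny = GenomeRecord("t", "ATG" + "GCT" * 20 + "TAA")
        with pytest.raises(ValueError, match="read_len"):
            sample_reads(_cfg([tiny], [1.0], 5, read_len=150))

    def test_bad_weights_rejected(self, fixture_genome):
        with pytest.raises(ValueError):
            _cfg([fixture_genome], [0.5], 5)


class TestRecoveryHarness:
    def test_noiseless_separated_community_recovers_perfectly(self):
        genomes = tuple(
            random_coding_genome(8000, seed=30 + i, genome_id=f"p{i}")
            for i in range(3)
        )
        com = Community(genomes, (0.6, 0.3, 0.1), decoys=())
        rho, table = recovery_harness(
            com, n_reads=600, error_rate=0.0, background_fraction=0.0, seed=4
        )
        assert rho == 1.0
        assert list(table["phage_id"]) == ["p0", "p1", "p2"]

    def test_degenerate_weights_rejected(self):
        genomes = tuple(
            random_coding_genome(8000, seed=40 + i, genome_id=f"q{i}")
            for i in range(3)
        )
        com = Community(genomes, (1 / 3, 1 / 3, 1 / 3), decoys=())
        with pytest.raises(ValueError):
            recovery_harness(com, n_reads=10, seed=1)
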