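"""Translated search engine: six-frame translation, the alignment DP
against an enumeration oracle, E-value statistics, and search modes."""

import math
from itertools import combinations

import numpy as np
import pytest

from virecruit.seqio import ReadRecord, reverse_complement
from virecruit.talign import (
    KarlinAltschulParams,
    ProteinIndex,
    bitscore,
    blosum62,
    evalue,
    local_align,
    local_align_score,
    search,
    six_frame_translate,
    write_hits_tsv,
)

MAT = blosum62()
FLAT = {(a, b): float(MAT[a, b]) for a in MAT.alphabet for b in MAT.alphabet}
AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_local_score(q, s, gap_open=11, gap_extend=1):
    """Independent oracle: enumerate every monotone matching of query
    positions to subject positions.  A local alignment is exactly a chain
    of substitution columns with affine-gap charges for the residues
    skipped between consecutive columns, so the optimum over all chains is
    the optimal local alignment score (floored at 0)."""

    def gap(d):
        return 0 if d == 0 else gap_open + gap_extend * d

    best = 0.0
    nq, ns = len(q), len(s)
    for k in range(1, min(nq, ns) + 1):
        for qi in combinations(range(nq), k):
            for si in combinations(range(ns), k):
                sc = FLAT[q[qi[0]], s[si[0]]]
                for t in range(1, k):
                    sc += FLAT[q[qi[t]], s[si[t]]]
                    sc -= gap(qi[t] - qi[t - 1] - 1) + gap(si[t] - si[t - 1] - 1)
                if sc > best:
                    best = sc
    return best


class TestSixFrame:
    def test_known_frames(self):
        frames = dict(six_frame_translate("ATGAAATAG"))
        assert frames[1] == "MK*"
        assert frames[-1] == "LFH"

    def test_too_short_gives_empty_peptides(self):
        assert all(pep == "" for _, pep in six_frame_translate("AT"))

    def test_revcomp_swaps_frame_sign(self):
        nt = "ATGGCAGATCCGAAATTTGGC"
        fwd = dict(six_frame_translate(nt))
        rev = dict(six_frame_translate(reverse_complement(nt)))
        assert fwd[1] == rev[-1] and fwd[-1] == rev[1]


class TestLocalAlign:
    def test_identical_triplet(self):
        aln = local_align("MKL", "MKL")
        assert aln.score == 14  # BLOSUM62 diagonal 5+5+4
        assert aln.pct_identity == 100.0

    def test_no_positive_alignment(self):
        assert local_align("AAAA", "WWWW") is None
        assert local_align_score("AAAA", "WWWW") == 0

    def test_dp_equals_enumeration_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            q = "".join(rng.choice(list(AA), rng.integers(2, 9)))
            s = "".join(rng.choice(list(AA), rng.integers(2, 9)))
            assert local_align_score(q, s) == brute_force_local_score(q, s), (q, s)

    def test_identity_counts_alignment_columns(self):
        aln = local_align("MKLVW", "MKIVW")
        assert aln.n_aligned == 5
        assert aln.n_identical == 4
        assert aln.pct_identity == 80.0


class TestEvalue:
    def test_direct_formula(self):
        assert evalue(80, 100, 10**6) == pytest.approx(2.2e-3, rel=0.02)

    def test_linear_in_n_and_m(self):
        e = evalue(50, 100, 10**6)
        assert evalue(50, 100, 2 * 10**6) == pytest.approx(2 * e)
        assert evalue(50, 200, 10**6) == pytest.approx(2 * e)

    def test_monotone_decay_in_score(self):
        es = [evalue(s, 100, 10**6) for s in (20, 40, 80, 160)]
        assert es == sorted(es, reverse=True)

    def test_bitscore_monotone_in_raw_score(self):
        bs = [bitscore(s) for s in (10, 20, 40)]
        assert bs == sorted(bs)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            evalue(50, 0, 100)
        with pytest.raises(ValueError):
            evalue(0, 100, 100)


class TestSearch:
    def test_self_match_reads_hit_at_full_identity(
        self, small_phage_orfs, coding_reads
    ):
        db = ProteinIndex({f"ORF{o.index}": o.protein for o in small_phage_orfs})
        hits = search(coding_reads, db, best_only=True)
        hit_reads = {h.read_id for h in hits}
        assert hit_reads == {r.id for r in coding_reads}
        assert all(h.pct_identity == 100.0 for h in hits)

    def test_seeded_equals_exhaustive(self, small_phage_orfs, coding_reads):
        db = ProteinIndex({f"ORF{o.index}": o.protein for o in small_phage_orfs})
        reads = coding_reads[:40]
        seeded = search(reads, db, mode="seeded")
        exhaustive = search(reads, db, mode="exhaustive")
        assert seeded == exhaustive

    def test_ranking_is_deterministic_total_order(self, small_phage_orfs, coding_reads):
        db = ProteinIndex({f"ORF{o.index}": o.protein for o in small_phage_orfs})
        reads = coding_reads[:20]
        a = search(reads, db)
        b = search(list(reads), db)
        assert a == b

    def test_revcomp_read_maps_to_mirror_frame(self, small_phage_orfs, coding_reads):
        db = ProteinIndex({f"ORF{o.index}": o.protein for o in small_phage_orfs})
        read = coding_reads[0]
        flipped = ReadRecord(read.id, reverse_complement(read.seq), "m1")
        (h1,) = search([read], db, best_only=True)
        (h2,) = search([flipped], db, best_only=True)
        assert h2.frame == -h1.frame
        assert h2.score == h1.score
        assert h2.subject_aa_span == h1.subject_aa_span

    def test_empty_read_collection(self, small_phage_orfs):
        db = ProteinIndex({f"ORF{o.index}": o.protein for o in small_phage_orfs})
        assert search([], db) == []

    def test_empty_db_rejected(self):
        with pytest.raises(ValueError):
            ProteinIndex({})

    def test_tsv_output_has_canonical_columns(self, small_phage_orfs, coding_reads, tmp_path):
        db = ProteinIndex({f"ORF{o.index}": o.protein for o in small_phage_orfs})
        hits = search(coding_reads[:5], db, best_only=True)
        out = tmp_path / "hits.tsv"
        write_hits_tsv(hits, out)
        header = out.read_text().splitlines()[0].split("\t")
        assert header == [
            "query", "subject", "pct_identity", "length", "mismatches",
            "gapopens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ]


def test_karlin_altschul_params_validated():
    with pytest.raises(ValueError):
        KarlinAltschulParams(lam=-1.0)
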