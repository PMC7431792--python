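"""Two-stage competitive recruitment and genome mapping."""

import pandas as pd
import pytest

from virecruit.seqio import Interval, ReadRecord
from virecruit.orfcall import OrfCall, call_orfs, proteome
from virecruit.recruit import (
    CompositeDB,
    competitive_assign,
    map_to_genome,
    read_recruitment_table,
    recruit_reads,
    screen,
    write_recruitment_table,
)

from conftest import excise_reads


@pytest.fixture(scope="module")
def focal_proteome(small_phage_orfs):
    return proteome(small_phage_orfs)


@pytest.fixture(scope="module")
def focal_db(small_phage, focal_proteome):
    return CompositeDB.from_proteomes(small_phage.id, {small_phage.id: focal_proteome})


@pytest.fixture(scope="module")
def composite_db(small_phage, small_decoy, focal_proteome):
    decoy_orfs = [o for o in call_orfs(small_decoy) if len(o.protein) >= 60]
    return CompositeDB.from_proteomes(
        small_phage.id,
        {small_phage.id: focal_proteome, small_decoy.id: proteome(decoy_orfs)},
    )


class TestScreen:
    def test_coding_reads_all_pass(self, coding_reads, focal_proteome):
        assert screen(coding_reads, focal_proteome) == list(coding_reads)

    def test_empty_read_set(self, focal_proteome):
        assert screen([], focal_proteome) == []

    def test_candidates_subset_of_reads(self, coding_reads, focal_proteome):
        mixed = list(coding_reads) + [
            ReadRecord(f"junk{i}", "ACGT" * 40, "m1") for i in range(5)
        ]
        cands = screen(mixed, focal_proteome)
        assert set(c.id for c in cands) <= set(r.id for r in mixed)


class TestCompetitiveAssign:
    def test_focal_only_db_recruits_all_candidates(
        self, coding_reads, focal_proteome, focal_db, small_phage_orfs
    ):
        cands = screen(coding_reads, focal_proteome)
        recruited = competitive_assign(cands, focal_db, small_phage_orfs)
        assert {r.read_id for r in recruited} == {c.id for c in cands}

    def test_decoys_never_enlarge_recruited_set(
        self, coding_reads, focal_proteome, focal_db, composite_db, small_phage_orfs
    ):
        cands = screen(coding_reads, focal_proteome)
        without = {r.read_id for r in competitive_assign(cands, focal_db, small_phage_orfs)}
        with_decoys = {
            r.read_id for r in competitive_assign(cands, composite_db, small_phage_orfs)
        }
        assert with_decoys <= without

    def test_outscoring_decoy_blocks_recruitment(self, small_phage, small_phage_orfs):
        # the decoy subject IS the read's protein; the focal subject differs
        orf = next(o for o in small_phage_orfs if len(o.protein) > 60)
        reads = excise_reads(small_phage, [orf], n_per_orf=1)
        variant = "M" + "A" * (len(orf.protein) - 1)  # unrelated focal protein
        db = CompositeDB.from_proteomes(
            small_phage.id,
            {small_phage.id: {orf.id: variant}, "decoyX": {orf.id: orf.protein}},
        )
        recruited = competitive_assign(reads, db, small_phage_orfs)
        assert recruited == []

    def test_exact_tie_resolved_by_subject_id(self, small_phage, small_phage_orfs):
        # identical protein under a focal id and a decoy id: focal ORF ids
        # sort before 'decoy|...' ids, so the tie goes to the focal phage
        orf = small_phage_orfs[0]
        reads = excise_reads(small_phage, [orf], n_per_orf=1)
        db = CompositeDB.from_proteomes(
            small_phage.id,
            {small_phage.id: {orf.id: orf.protein}, "zdecoy": {orf.id: orf.protein}},
        )
        recruited = competitive_assign(reads, db, small_phage_orfs)
        assert {r.read_id for r in recruited} == {r.id for r in reads}
        r2 = competitive_assign(reads, db, small_phage_orfs)
        assert recruited == r2

    def test_db_without_focal_rejected(self, focal_proteome):
        with pytest.raises(ValueError, match="focal"):
            CompositeDB.from_proteomes("nope", {"other": focal_proteome})


class TestContainmentChain:
    def test_recruited_subset_candidates_subset_reads(
        self, coding_reads, focal_proteome, composite_db, small_phage_orfs
    ):
        mixed = list(coding_reads) + [
            ReadRecord(f"bg{i}", "TGCA" * 40, "m1") for i in range(5)
        ]
        candidates, recruited = recruit_reads(
            mixed, focal_proteome, composite_db, small_phage_orfs
        )
        read_ids = {r.id for r in mixed}
        cand_ids = {c.id for c in candidates}
        rec_ids = {r.read_id for r in recruited}
        assert rec_ids <= cand_ids <= read_ids

    def test_record_interval_inside_orf(
        self, coding_reads, focal_proteome, focal_db, small_phage_orfs
    ):
        _, recruited = recruit_reads(
            coding_reads, focal_proteome, focal_db, small_phage_orfs
        )
        by_index = {o.index: o for o in small_phage_orfs}
        assert recruited
        for rec in recruited:
            orf = by_index[rec.orf_index]
            assert orf.interval.start <= rec.genome_interval.start
            assert rec.genome_interval.end <= orf.interval.end
            span = rec.genome_interval.end - rec.genome_interval.start + 1
            assert span % 3 == 0


class TestMapToGenome:
    def _orf(self, start, end, strand, protein):
        return OrfCall(1, Interval(start, end, strand), protein, "x", "g")

    def test_plus_strand_arithmetic(self):
        orf = self._orf(101, 160, "+", "M" * 19)
        iv = map_to_genome(orf, (1, 10))
        assert (iv.start, iv.end, iv.strand) == (101, 130, "+")

    def test_minus_strand_mirror(self):
        orf = self._orf(200, 259, "-", "M" * 19)
        iv = map_to_genome(orf, (1, 10))
        assert (iv.start, iv.end, iv.strand) == (230, 259, "-")

    def test_full_protein_excludes_stop(self):
        orf = self._orf(101, 160, "+", "M" * 19)
        iv = map_to_genome(orf, (1, 19))
        assert (iv.start, iv.end) == (101, 157)

    def test_span_beyond_protein_rejected(self):
        orf = self._orf(101, 160, "+", "M" * 19)
        with pytest.raises(ValueError):
            map_to_genome(orf, (1, 20))


class TestRecruitmentTable:
    def test_empty_records_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_recruitment_table([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("metagenome_id\tread_id")

    def test_round_trip(
        self, coding_reads, focal_proteome, focal_db, small_phage_orfs, tmp_path
    ):
        _, recruited = recruit_reads(
            coding_reads[:10], focal_proteome, focal_db, small_phage_orfs
        )
        p = tmp_path / "r.tsv"
        write_recruitment_table(recruited, p)
        df = read_recruitment_table(p)
        assert len(df) == len(recruited)
        assert list(df["genome_start"]) == sorted(df["genome_start"])
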