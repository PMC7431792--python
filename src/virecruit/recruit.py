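"""Two-stage competitive fragment recruitment.

Stage 1 (*screen*) finds reads with a translated hit (E <= cutoff) against
the focal phage's proteome.  Stage 2 (*competitive assignment*) searches
each candidate against a composite database of the focal proteome plus
decoy phage proteomes and recruits the read only if its best hit — under
the deterministic ranking bitscore desc, E asc, subject id asc — belongs to
the focal phage.  Recruited reads are mapped back onto focal-genome
nucleotide coordinates through the ORF that matched, giving the data table
behind a fragment-recruitment plot.

Competition uses a true deterministic best hit over the whole database
rather than a "first target only" shortcut, so results are independent of
database ordering.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .seqio import Interval, ReadRecord
from .orfcall import OrfCall
from .talign import AlignmentHit, KarlinAltschulParams, ProteinIndex, search

__all__ = [
    "CompositeDB",
    "RecruitmentRecord",
    "screen",
    "competitive_assign",
    "map_to_genome",
    "write_recruitment_table",
    "read_recruitment_table",
    "recruit_reads",
]

RECRUITMENT_COLUMNS = [
    "metagenome_id",
    "read_id",
    "genome_start",
    "genome_end",
    "pct_identity",
    "evalue",
    "bitscore",
    "orf_index",
]


class CompositeDB(ProteinIndex):
    """Focal proteome plus decoy phage proteomes, indexed for search.

    Subject ids must be globally unique; ``phage_of`` maps each subject to
    its phage, and the focal phage's proteins must be present.
    """

    def __init__(
        self,
        focal_phage_id: str,
        proteins: Mapping[str, str],
        phage_of: Mapping[str, str],
    ):
        super().__init__(proteins, phage_of)
        if focal_phage_id not in set(self.phage_of.values()):
            raise ValueError(
                f"composite database lacks focal phage {focal_phage_id!r}"
            )
        self.focal_phage_id = focal_phage_id

    @classmethod
    def from_proteomes(
        cls, focal_phage_id: str, proteomes: Mapping[str, Mapping[str, str]]
    ) -> "CompositeDB":
        """Build from {phage_id: {orf_id: peptide}}; subject ids are
        namespaced as '<phage_id>|<orf_id>' except for the focal phage,
        whose ORF ids are kept bare so they match the annotation."""
        proteins: dict[str, str] = {}
        phage_of: dict[str, str] = {}
        for phage_id, prot in proteomes.items():
            for orf_id, pep in prot.items():
                sid = orf_id if phage_id == focal_phage_id else f"{phage_id}|{orf_id}"
                proteins[sid] = pep
                phage_of[sid] = phage_id
        return cls(focal_phage_id, proteins, phage_of)

    @property
    def decoy_phage_count(self) -> int:
        return len(set(self.phage_of.values())) - 1


@dataclass(frozen=True)
class RecruitmentRecord:
    """A read accepted as focal-phage-like, mapped onto the focal genome."""

    read_id: str
    source_metagenome: str
    best_subject: str  # focal ORF id
    orf_index: int
    genome_interval: Interval
    pct_identity: float
    evalue: float
    bitscore: float


def screen(
    reads: Sequence[ReadRecord],
    focal_proteome: Mapping[str, str] | ProteinIndex,
    cutoff: float = 1e-5,
    mode: str = "seeded",
    params: KarlinAltschulParams | None = None,
) -> list[ReadRecord]:
    """Stage 1: the subset of reads with at least one translated hit at
    E <= cutoff against the focal proteome, in input order."""
    if not isinstance(focal_proteome, ProteinIndex):
        focal_proteome = ProteinIndex(focal_proteome)
    hits = search(reads, focal_proteome, cutoff=cutoff, mode=mode, params=params,
                  best_only=True)
    with_hit = {h.read_id for h in hits}
    return [r for r in reads if r.id in with_hit]


def map_to_genome(orf: OrfCall, subject_aa_span: tuple[int, int]) -> Interval:
    """Map an amino-acid span on a focal ORF's protein to nucleotide
    coordinates on the focal genome.

    For a plus-strand ORF at [g1, g2], aa span [a1, a2] maps to
    [g1 + 3(a1-1), g1 + 3*a2 - 1]; minus-strand ORFs map mirror-image from
    g2 downward.  The result always lies inside the ORF (the stop codon is
    never part of a protein span).
    """
    a1, a2 = subject_aa_span
    if not (1 <= a1 <= a2 <= len(orf.protein)):
        raise ValueError(
            f"aa span {subject_aa_span} outside protein of length {len(orf.protein)}"
        )
    g1, g2 = orf.interval.start, orf.interval.end
    if orf.interval.strand == "+":
        return Interval(g1 + 3 * (a1 - 1), g1 + 3 * a2 - 1, "+")
    return Interval(g2 - 3 * a2 + 1, g2 - 3 * (a1 - 1), "-")


def competitive_assign(
    candidates: Sequence[ReadRecord],
    db: CompositeDB,
    orfs: Sequence[OrfCall],
    cutoff: float = 1e-5,
    mode: str = "seeded",
    params: KarlinAltschulParams | None = None,
) -> list[RecruitmentRecord]:
    """Stage 2: search candidates against the composite database and
    recruit each read whose deterministic best hit is a focal protein.

    Ties in (bitscore, E) are broken by subject id ascending, so a read
    tied between a focal and a decoy subject is resolved reproducibly.
    """
    by_id = {f"ORF{c.index}": c for c in orfs}
    by_read = {r.id: r for r in candidates}
    best = search(
        candidates, db, cutoff=cutoff, mode=mode, params=params, best_only=True
    )
    records = []
    for hit in best:
        if db.phage_of[hit.subject_id] != db.focal_phage_id:
            continue
        orf = by_id.get(hit.subject_id)
        if orf is None:
            raise ValueError(f"best hit {hit.subject_id} not in focal annotation")
        read = by_read[hit.read_id]
        records.append(
            RecruitmentRecord(
                read_id=hit.read_id,
                source_metagenome=read.source_metagenome,
                best_subject=hit.subject_id,
                orf_index=orf.index,
                genome_interval=map_to_genome(orf, hit.subject_aa_span),
                pct_identity=hit.pct_identity,
                evalue=hit.evalue,
                bitscore=hit.bitscore,
            )
        )
    return records


def recruit_reads(
    reads: Sequence[ReadRecord],
    focal_proteome: Mapping[str, str],
    db: CompositeDB,
    orfs: Sequence[OrfCall],
    cutoff: float = 1e-5,
    mode: str = "seeded",
    params: KarlinAltschulParams | None = None,
) -> tuple[list[ReadRecord], list[RecruitmentRecord]]:
    """Run both stages; returns (stage-1 candidates, recruited records)."""
    candidates = screen(reads, focal_proteome, cutoff=cutoff, mode=mode, params=params)
    recruited = competitive_assign(
        candidates, db, orfs, cutoff=cutoff, mode=mode, params=params
    )
    return candidates, recruited


def write_recruitment_table(records: Sequence[RecruitmentRecord], path) -> None:
    """TSV of recruited reads sorted by genome start then read id; an empty
    record set writes the header only.  Origin-spanning interval
    coordinates are written unwrapped (end may exceed the genome length)."""
    df = recruitment_frame(records)
    df.to_csv(path, sep="\t", index=False)


def recruitment_frame(records: Sequence[RecruitmentRecord]) -> pd.DataFrame:
    rows = [
        {
            "metagenome_id": r.source_metagenome,
            "read_id": r.read_id,
            "genome_start": r.genome_interval.start,
            "genome_end": r.genome_interval.end,
            "pct_identity": round(r.pct_identity, 2),
            "evalue": r.evalue,
            "bitscore": round(r.bitscore, 1),
            "orf_index": r.orf_index,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=RECRUITMENT_COLUMNS)
    return df.sort_values(["genome_start", "read_id"]).reset_index(drop=True)


def read_recruitment_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
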