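"""ORF prediction on (possibly circular) phage genomes plus the two-caller
consensus rule.

The module ships one simple maximal-ORF caller (every start-to-stop frame on
both strands above a span threshold, bacterial genetic code) and a consensus
combiner that merges any two call sets — including call sets imported from
external gene finders via GFF3 — by keeping, at each locus where the two
callers disagree, the longer prediction.  Loci are identified by
(stop-codon position, strand): gene finders disagree mostly on start choice,
so two calls sharing a stop are alternative starts of one gene and "the
longer" is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

from .seqio import GenomeRecord, Interval, reverse_complement, write_gff3, read_gff3

__all__ = [
    "OrfCall",
    "OrfConfig",
    "call_orfs",
    "consensus_longer",
    "translate_orf",
    "orf_subsequence",
    "proteome",
    "write_orfs_gff3",
    "read_orfs_gff3",
    "write_proteome_fasta",
]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_STOP_CODONS = frozenset(_TABLE11.stop_codons)  # TAA, TAG, TGA


@dataclass(frozen=True)
class OrfConfig:
    """Caller configuration.

    ``min_len_nt`` filters on the full nucleotide span including the stop
    codon, with a strict ``>`` comparison (an ORF of exactly ``min_len_nt``
    is dropped).  Start codons default to the common bacterial set.
    """

    min_len_nt: int = 100
    genetic_code: int = 11
    start_codons: frozenset[str] = frozenset({"ATG", "GTG", "TTG"})

    def __post_init__(self) -> None:
        if self.min_len_nt < 3:
            raise ValueError("min_len_nt must be >= 3")


@dataclass(frozen=True)
class OrfCall:
    """A strand-aware coding interval with its translated protein.

    ``interval`` is on forward-genome coordinates (canonical start <= end;
    for origin-spanning ORFs on circular genomes, end may exceed the genome
    length — unwrapped coordinates).  ``protein`` excludes the stop codon,
    so span length = 3 * (len(protein) + 1).
    """

    index: int
    interval: Interval
    protein: str
    caller: str = "virecruit"
    genome_id: str = ""

    @property
    def id(self) -> str:
        return f"ORF{self.index}"

    def span_nt(self) -> int:
        return self.interval.end - self.interval.start + 1

    def stop_key(self) -> tuple[str, str, int]:
        """Locus identity: (genome, strand, stop-codon anchor position).

        The anchor is the genome coordinate of the stop codon's outermost
        base: ``end`` for plus-strand ORFs, ``start`` for minus-strand ones.
        """
        anchor = self.interval.end if self.interval.strand == "+" else self.interval.start
        return (self.genome_id, self.interval.strand, anchor)


def _translate_cds(nt: str, start_codons: frozenset[str]) -> str:
    """Translate a stop-terminated CDS with code 11; the initiator codon is
    rendered M when it is a recognised start codon (bacterial convention)."""
    if len(nt) % 3 != 0:
        raise ValueError(f"CDS length {len(nt)} not divisible by 3")
    aa = str(Seq(nt).translate(table=11))
    if not aa.endswith("*"):
        raise ValueError("CDS does not end in a stop codon")
    aa = aa[:-1]
    if "*" in aa:
        raise ValueError("internal stop codon in CDS (coordinate bug?)")
    if nt[:3] in start_codons and aa:
        aa = "M" + aa[1:]
    return aa


def orf_subsequence(genome: GenomeRecord, iv: Interval) -> str:
    """Extract the coding-strand nucleotide sequence of an interval,
    unwrapping across the origin of circular genomes when end > length."""
    L = len(genome.seq)
    if iv.end <= L:
        nt = genome.seq[iv.start - 1 : iv.end]
    else:
        if not genome.circular:
            raise ValueError(f"interval end {iv.end} beyond linear genome of {L} bp")
        if iv.end - iv.start + 1 > L:
            raise ValueError("interval longer than the circular genome")
        nt = genome.seq[iv.start - 1 :] + genome.seq[: iv.end - L]
    return nt if iv.strand == "+" else reverse_complement(nt)


def translate_orf(
    genome: GenomeRecord, iv: Interval,
    start_codons: frozenset[str] = OrfConfig.start_codons,
) -> str:
    """Translate the ORF at ``iv`` (stop codon included in the interval,
    excluded from the protein); minus-strand ORFs are translated from the
    reverse complement."""
    return _translate_cds(orf_subsequence(genome, iv), start_codons)


def _scan_strand(
    seq: str, L: int, strand: str, circular: bool, cfg: OrfConfig,
) -> list[tuple[int, int, str, str]]:
    """Find maximal start-to-stop ORFs on one strand of a working sequence.

    Returns (g1, g2, strand, cds) in forward-genome coordinates, with
    origin-spanning intervals unwrapped (g2 may exceed L).  ``seq`` is the
    forward sequence for '+', the reverse complement for '-'.  For circular
    genomes the scan runs over the sequence virtually extended across the
    origin by one full copy (plus two bases so every codon window closes),
    and an ORF is recorded only once its preceding in-frame stop has been
    seen — this makes the call set independent of the rotation point;
    duplicates from the extra copy are removed by their stop-codon anchor.
    """
    work = seq + (seq + seq[:2] if circular else "")
    n = len(work)
    out = []
    for frame in range(3):
        start_w: int | None = None  # working coord of current leftmost start
        stop_seen = not circular  # circular scans need upstream stop context
        w = frame
        while w + 3 <= n:
            codon = work[w : w + 3]
            if codon in _STOP_CODONS:
                if start_w is not None and stop_seen:
                    span = w + 3 - start_w
                    if span > cfg.min_len_nt and span <= L:
                        out.append((start_w, w + 3))
                start_w = None
                stop_seen = True
            elif start_w is None and codon in cfg.start_codons:
                start_w = w
            w += 3
    calls = []
    seen: set[tuple[int, str]] = set()
    for sw, ew in out:  # working half-open [sw, ew)
        span = ew - sw
        sw = sw % L
        ew = sw + span
        cds = work[sw:ew]  # ew <= 2L < len(work) after the shift
        if strand == "+":
            g1, g2 = sw + 1, ew
        else:
            # working coords count from the 5' end of the revcomp;
            # mirror back onto forward 1-based coordinates
            g1, g2 = L - ew + 1, L - sw
            if g1 < 1:  # spans the origin: unwrap into [1, 2L)
                g1 += L
                g2 += L
        # the stop codon's outermost base anchors the locus
        anchor = (g2 - 1) % L if strand == "+" else (g1 - 1) % L
        if (anchor, strand) in seen:
            continue
        seen.add((anchor, strand))
        calls.append((g1, g2, strand, cds))
    return calls


def call_orfs(genome: GenomeRecord, cfg: OrfConfig | None = None) -> list[OrfCall]:
    """Predict every maximal start-to-stop ORF on both strands with span
    strictly greater than ``cfg.min_len_nt``.

    For circular genomes the sequence is virtually extended across the
    origin by one full copy minus 1 nt, so origin-spanning ORFs are found
    exactly once (reported with unwrapped end > genome length).  Output is
    sorted by start coordinate and indexed 1..n in that order.
    """
    cfg = cfg or OrfConfig()
    L = len(genome.seq)
    if L < cfg.min_len_nt:
        raise ValueError(f"genome shorter ({L} nt) than min_len_nt")
    picked = _scan_strand(genome.seq, L, "+", genome.circular, cfg)
    picked += _scan_strand(reverse_complement(genome.seq), L, "-", genome.circular, cfg)
    picked.sort(key=lambda t: (t[0], t[1], t[2]))
    calls = []
    for i, (g1, g2, strand, cds) in enumerate(picked, 1):
        protein = _translate_cds(cds, cfg.start_codons)
        calls.append(
            OrfCall(i, Interval(g1, g2, strand), protein, "virecruit", genome.id)
        )
    return calls


def consensus_longer(
    calls_a: Sequence[OrfCall], calls_b: Sequence[OrfCall]
) -> list[OrfCall]:
    """Merge two call sets for the same genome, keeping the longer call at
    each shared locus.

    A locus is (stop position, strand); where both callers report the locus
    the longer span wins (tie: smaller start offset, i.e. the calls are
    identical by construction), and a locus seen by only one caller is kept
    as-is.  Output is re-sorted and re-indexed by start.
    """
    genomes = {c.genome_id for c in calls_a} | {c.genome_id for c in calls_b}
    if len(genomes) > 1:
        raise ValueError(f"calls from different genomes: {sorted(genomes)}")
    chosen: dict[tuple, OrfCall] = {}
    for c in list(calls_a) + list(calls_b):
        key = c.stop_key()
        prev = chosen.get(key)
        if prev is None or c.span_nt() > prev.span_nt():
            chosen[key] = c
    merged = sorted(
        chosen.values(), key=lambda c: (c.interval.start, c.interval.end, c.interval.strand)
    )
    return [replace(c, index=i) for i, c in enumerate(merged, 1)]


def proteome(orfs: Sequence[OrfCall]) -> dict[str, str]:
    """Map ORF id ("ORF<n>") to protein sequence."""
    return {c.id: c.protein for c in orfs}


def write_orfs_gff3(orfs: Sequence[OrfCall], genome_id: str, path) -> None:
    feats = [
        {
            "seqid": genome_id,
            "source": c.caller,
            "type": "CDS",
            "start": c.interval.start,
            "end": c.interval.end,
            "score": None,
            "strand": c.interval.strand,
            "attributes": {"ID": c.id},
        }
        for c in orfs
    ]
    write_gff3(feats, path)


def read_orfs_gff3(path, genome: GenomeRecord, caller: str = "imported") -> list[OrfCall]:
    """Import CDS features from an external gene finder's GFF3; proteins are
    re-derived from the genome so coordinate/protein coherence holds."""
    calls = []
    for i, f in enumerate((f for f in read_gff3(path) if f["type"] == "CDS"), 1):
        iv = Interval(f["start"], f["end"], f["strand"])
        calls.append(
            OrfCall(i, iv, translate_orf(genome, iv), caller, genome.id)
        )
    return calls


def write_proteome_fasta(orfs: Sequence[OrfCall], path) -> None:
    with open(path, "w") as fh:
        for c in orfs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.protein), 70):
                fh.write(c.protein[i : i + 70] + "\n")
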