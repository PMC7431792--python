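"""Sequence and feature I/O, plus the coordinate conventions used pipeline-wide.

Coordinates are 1-based and fully inclusive throughout, matching the
conventions of printed phage annotation tables.  The internal canonical form
of an interval always has ``start <= end`` with strand carried separately,
because published tables are inconsistent on this point (some encode the
minus strand as ``start > end``, others list a strand column with
``start < end``).  :func:`write_intervals_tsv`-style writers can emit either
dialect.

Only plain-text formats are handled: FASTA for genomes/proteins/reads,
FASTQ for reads (qualities ignored), GFF3 for features, TSV for tables.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeRecord",
    "Interval",
    "ReadRecord",
    "FastaFormatError",
    "read_fasta",
    "write_fasta",
    "read_reads",
    "interval_length",
    "normalize_interval",
    "intervals_overlap",
    "gc_content",
    "at_content",
    "reverse_complement",
    "read_gff3",
    "write_gff3",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class FastaFormatError(ValueError):
    """Raised when a sequence file violates the FASTA grammar."""


@dataclass(frozen=True)
class GenomeRecord:
    """A (possibly circular) nucleotide sequence.

    ``seq`` is stored uppercase over the alphabet {A, C, G, T, N}.  For
    circular genomes the linear representation starts at an arbitrary
    rotation point; downstream code unwraps across the origin where needed.
    """

    id: str
    seq: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc(self) -> float:
        return gc_content(self.seq)


@dataclass(frozen=True, order=True)
class Interval:
    """A strand-aware 1-based fully-inclusive genomic interval.

    Canonical form has ``start <= end``; use :func:`normalize_interval` to
    canonicalise table rows that encode strand by coordinate order.  For
    features spanning the origin of a circular genome, ``end`` may exceed the
    genome length (unwrapped coordinates); callers wrap with ``% L`` when a
    physical position is needed.
    """

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1:
            raise ValueError(f"1-based start must be >= 1, got {self.start}")


@dataclass(frozen=True)
class ReadRecord:
    """A metagenomic read tagged with its source metagenome."""

    id: str
    seq: str
    source_metagenome: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


def normalize_interval(start: int, end: int, strand: str | None = None) -> Interval:
    """Canonicalise a possibly start>end coordinate pair.

    Tables that encode the minus strand as ``start > end`` are converted to
    the canonical ``start <= end`` form; if ``strand`` is given explicitly it
    wins, otherwise ``start > end`` implies the minus strand.
    """
    if start > end:
        start, end = end, start
        if strand is None:
            strand = "-"
    return Interval(start, end, strand or "+")


def interval_length(iv: Interval | tuple) -> int:
    """Length in bp of a 1-based inclusive interval: ``|end - start| + 1``."""
    if isinstance(iv, tuple):
        iv = normalize_interval(iv[0], iv[1], iv[2] if len(iv) > 2 else None)
    return abs(iv.end - iv.start) + 1


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a.start <= b.end and b.start <= a.end


def gc_content(seq: str) -> float:
    """Percent G+C over the A/C/G/T content of ``seq``; N is excluded
    from the denominator.  Raises on an all-N (or empty) sequence."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    denom = gc + s.count("A") + s.count("T")
    if denom == 0:
        raise ValueError("GC content undefined: no A/C/G/T bases")
    return 100.0 * gc / denom


def at_content(seq: str) -> float:
    return 100.0 - gc_content(seq)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_fasta_grammar(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected FASTA header '>' "
                    f"before sequence data"
                )
            return  # first non-blank line is a header; Biopython handles the rest


def read_fasta(
    path: str | Path, *, circular: bool = False, as_reads: bool = False,
    source_metagenome: str = "",
) -> list[GenomeRecord] | list[ReadRecord]:
    """Read a FASTA file into :class:`GenomeRecord` (default) or
    :class:`ReadRecord` (``as_reads=True``) objects.

    Sequences are uppercased and line wrapping removed; the description
    after the first whitespace is kept separately from the id.  An empty
    file yields an empty list; a file whose first record lacks a '>'
    header raises :class:`FastaFormatError` naming the line.
    """
    path = Path(path)
    _check_fasta_grammar(path)
    out: list = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        if as_reads:
            out.append(ReadRecord(rec.id, str(rec.seq), source_metagenome))
        else:
            out.append(GenomeRecord(rec.id, str(rec.seq), circular, desc))
    ids = [r.id for r in out]
    if len(set(ids)) != len(ids):
        raise FastaFormatError(f"{path}: duplicate record ids")
    return out


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write records (anything with .id and .seq) as wrapped FASTA."""
    seqrecs = []
    for r in records:
        desc = getattr(r, "description", "")
        seqrecs.append(SeqRecord(Seq(r.seq), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_reads(path: str | Path, source_metagenome: str = "") -> list[ReadRecord]:
    """Read metagenomic reads from FASTA or FASTQ (sniffed from the first
    byte); FASTQ qualities are discarded."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return [
            ReadRecord(rec.id, str(rec.seq), source_metagenome)
            for rec in SeqIO.parse(str(path), "fastq")
        ]
    return read_fasta(path, as_reads=True, source_metagenome=source_metagenome)


# --- GFF3 -------------------------------------------------------------------
# Feature output/input is a flat 9-column GFF3 table (1-based inclusive,
# column 7 strand); no hierarchy is needed so a thin reader/writer suffices.

def read_gff3(path: str | Path) -> list[dict]:
    """Parse GFF3 into a list of dicts with keys seqid, source, type,
    start, end, score, strand, attributes (dict)."""
    feats: list[dict] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected 9 GFF3 columns, got {len(cols)}"
                )
            attrs = {}
            for item in cols[8].split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attrs[k.strip()] = v.strip()
            feats.append(
                {
                    "seqid": cols[0],
                    "source": cols[1],
                    "type": cols[2],
                    "start": int(cols[3]),
                    "end": int(cols[4]),
                    "score": None if cols[5] == "." else float(cols[5]),
                    "strand": cols[6],
                    "attributes": attrs,
                }
            )
    return feats


def write_gff3(features: Sequence[dict], path: str | Path) -> None:
    """Write features (dicts as produced by :func:`read_gff3`) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f["attributes"].items())
            score = "." if f.get("score") is None else f"{f['score']:g}"
            fh.write(
                "\t".join(
                    [
                        f["seqid"],
                        f.get("source", "virecruit"),
                        f["type"],
                        str(f["start"]),
                        str(f["end"]),
                        score,
                        f["strand"],
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
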