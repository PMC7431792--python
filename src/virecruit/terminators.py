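"""Simplified rho-independent terminator screen.

Intrinsic terminators are RNA stem-loops followed by a U-rich tract.  The
screen here is deliberately transparent: candidate hairpins are inverted
repeats whose stem pairs come from an explicit pairing table (G:C, A:T and
the G:U wobble), scored as the sum of pair energies plus a loop-size
penalty, filtered at an energy threshold (default -16 kcal/mol) and — to
suppress random hairpins — required to be followed within a few bases by a
poly-T tract on the coding strand.  Every reported energy is exactly
reproducible from the stated table, which is the point of the model; it is
not a nearest-neighbor thermodynamic calculation.

Each call is annotated with the nearest upstream ORF on the same strand
within a configurable distance, mirroring the standard terminator-table
layout (terminator, coordinates, length, strand, energy, upstream ORF,
distance).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .seqio import GenomeRecord, Interval, reverse_complement, write_gff3
from .orfcall import OrfCall

__all__ = [
    "TerminatorCall",
    "TerminatorConfig",
    "hairpin_energy",
    "find_terminators",
    "write_terminators_tsv",
    "write_terminators_gff3",
]

# kcal/mol per closed stem pair; keys are (coding-strand 5' arm base,
# coding-strand 3' arm base) read as an RNA pair after transcription
_PAIR_ENERGY: dict[frozenset[str] | tuple[str, str], float] = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}


@dataclass(frozen=True)
class TerminatorConfig:
    """Screen parameters.

    ``energy_threshold`` (kcal/mol, negative) is the acceptance cutoff;
    stem and loop bounds delimit the inverted-repeat search; the loop
    penalty is +4.0 kcal at the minimum loop of 3 nt plus 0.3 kcal per
    extra loop base.  ``require_t_tail`` demands >= ``min_t_run`` T's
    within ``tail_window`` nt downstream of the hairpin.
    """

    energy_threshold: float = -16.0
    min_stem: int = 4
    max_stem: int = 20
    min_loop: int = 3
    max_loop: int = 10
    loop_penalty_base: float = 4.0
    loop_penalty_per_nt: float = 0.3
    max_orf_distance: int = 200
    require_t_tail: bool = True
    min_t_run: int = 4
    tail_window: int = 5

    def __post_init__(self) -> None:
        if self.energy_threshold >= 0:
            raise ValueError("energy threshold must be negative")


@dataclass(frozen=True)
class TerminatorCall:
    """A reported terminator: interval spans the hairpin through the end of
    its poly-T tract on forward-genome coordinates."""

    interval: Interval
    energy_kcal: float
    stem_len: int
    loop_len: int
    upstream_orf: int | None
    distance_nt: int | None


def hairpin_energy(
    stem_pairs: Sequence[tuple[str, str]], loop_len: int,
    cfg: TerminatorConfig | None = None,
) -> float:
    """Energy (kcal/mol) of a hairpin given its stem pairs (5' arm base,
    3' arm base) and loop length: sum of pair energies plus the loop
    penalty.  A pair outside the allowed set is an error."""
    cfg = cfg or TerminatorConfig()
    if not stem_pairs:
        raise ValueError("stem must contain at least one pair")
    total = 0.0
    for pair in stem_pairs:
        key = (pair[0].upper(), pair[1].upper())
        if key not in _PAIR_ENERGY:
            raise ValueError(f"disallowed stem pair {key}")
        total += _PAIR_ENERGY[key]
    total += cfg.loop_penalty_base + cfg.loop_penalty_per_nt * (loop_len - cfg.min_loop)
    return total


def _scan_one_strand(seq: str, cfg: TerminatorConfig):
    """Yield (start0, hp_end0, tail_end0, stem, loop, energy) candidates on
    one strand; coordinates are 0-based half-open on ``seq``.  For each
    hairpin start, only the maximal qualifying stem per loop size is kept."""
    n = len(seq)
    for ls in range(1, n):  # 0-based loop start
        for loop in range(cfg.min_loop, cfg.max_loop + 1):
            # grow the stem outward from the loop: pair k closes
            # (seq[ls-1-k], seq[ls+loop+k]); the stem is maximal by
            # construction
            stem = 0
            energy = 0.0
            while stem < cfg.max_stem:
                a_i = ls - 1 - stem
                b_i = ls + loop + stem
                if a_i < 0 or b_i >= n:
                    break
                e = _PAIR_ENERGY.get((seq[a_i], seq[b_i]))
                if e is None:
                    break
                energy += e
                stem += 1
            if stem < cfg.min_stem:
                continue
            energy += cfg.loop_penalty_base + cfg.loop_penalty_per_nt * (
                loop - cfg.min_loop
            )
            i0 = ls - stem
            j0 = ls + loop + stem  # half-open end of hairpin
            if energy > cfg.energy_threshold:
                continue
            tail_end = j0
            if cfg.require_t_tail:
                window = seq[j0 : j0 + cfg.tail_window + cfg.min_t_run]
                run_start = None
                run = 0
                found = False
                for off, base in enumerate(window):
                    if base == "T":
                        if run == 0:
                            run_start = off
                        run += 1
                        if run >= cfg.min_t_run and run_start <= cfg.tail_window:
                            found = True
                    else:
                        run = 0
                if not found:
                    continue
                # extend the reported interval through the contiguous T run
                k = j0
                while k < n and seq[k] != "T":
                    k += 1
                while k < n and seq[k] == "T":
                    k += 1
                tail_end = k
            yield (i0, j0, tail_end, stem, loop, energy)


def _annotate_upstream(
    call_iv: Interval, orfs: Sequence[OrfCall], cfg: TerminatorConfig
) -> tuple[int | None, int | None]:
    """Nearest same-strand upstream ORF within max_orf_distance; distance is
    the gap between the ORF 3' end and the terminator 5' end."""
    best: tuple[int, int] | None = None
    for orf in orfs:
        if orf.interval.strand != call_iv.strand:
            continue
        if call_iv.strand == "+":
            gap = call_iv.start - orf.interval.end - 1
        else:
            gap = orf.interval.start - call_iv.end - 1
        if 0 <= gap <= cfg.max_orf_distance and (best is None or gap < best[1]):
            best = (orf.index, gap)
    return best if best else (None, None)


def find_terminators(
    genome: GenomeRecord,
    orfs: Sequence[OrfCall] = (),
    cfg: TerminatorConfig | None = None,
) -> list[TerminatorCall]:
    """Scan both strands for thresholded stem-loop + poly-T candidates and
    keep the lowest-energy non-overlapping set.

    Overlap resolution: candidates are ranked energy ascending (most
    stable first), ties broken by leftmost start then '+' strand, and
    accepted greedily if they do not overlap an accepted call.
    """
    cfg = cfg or TerminatorConfig()
    L = len(genome.seq)
    cands: list[tuple[float, int, str, Interval, int, int]] = []
    for i0, _j0, t0, stem, loop, energy in _scan_one_strand(genome.seq, cfg):
        iv = Interval(i0 + 1, t0, "+")
        cands.append((energy, iv.start, "+", iv, stem, loop))
    rc = reverse_complement(genome.seq)
    for i0, _j0, t0, stem, loop, energy in _scan_one_strand(rc, cfg):
        iv = Interval(L - t0 + 1, L - i0, "-")
        cands.append((energy, iv.start, "-", iv, stem, loop))
    cands.sort(key=lambda t: (t[0], t[1], 0 if t[2] == "+" else 1))
    accepted: list[TerminatorCall] = []
    for energy, _s, _st, iv, stem, loop in cands:
        if any(
            iv.start <= a.interval.end and a.interval.start <= iv.end
            for a in accepted
        ):
            continue
        orf_idx, dist = _annotate_upstream(iv, orfs, cfg)
        accepted.append(TerminatorCall(iv, energy, stem, loop, orf_idx, dist))
    accepted.sort(key=lambda c: (c.interval.start, c.interval.strand))
    return accepted


def write_terminators_tsv(calls: Sequence[TerminatorCall], path) -> None:
    """Write calls in the conventional terminator-table column order."""
    with open(path, "w") as fh:
        fh.write(
            "Terminator\tStart\tEnd\tLength (bp)\tStrand\tEnergy (kCal)\t"
            "Upstream ORF\tDistance to ORF\n"
        )
        for i, c in enumerate(calls, 1):
            orf = "" if c.upstream_orf is None else str(c.upstream_orf)
            dist = "" if c.distance_nt is None else str(c.distance_nt)
            fh.write(
                f"Term{i}\t{c.interval.start}\t{c.interval.end}\t"
                f"{c.interval.end - c.interval.start + 1}\t{c.interval.strand}\t"
                f"{c.energy_kcal:.1f}\t{orf}\t{dist}\n"
            )


def write_terminators_gff3(
    calls: Sequence[TerminatorCall], genome_id: str, path
) -> None:
    feats = [
        {
            "seqid": genome_id,
            "source": "virecruit",
            "type": "terminator",
            "start": c.interval.start,
            "end": c.interval.end,
            "score": c.energy_kcal,
            "strand": c.interval.strand,
            "attributes": {"ID": f"Term{i}"},
        }
        for i, c in enumerate(calls, 1)
    ]
    write_gff3(feats, path)
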