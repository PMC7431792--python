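"""Synthetic phage communities with known ground truth.

The generator emulates the statistical structure the recruitment analysis
assumes about an environmental virome: a community of related phage
genomes present at known relative abundances, controlled amino-acid-level
divergence from a focal genome, fixed-length shotgun reads with uniform
substitution errors, and a background of non-homologous random sequence.
It deliberately omits indels (so genome coordinates stay comparable to
truth and amino-acid identity is directly controllable), quality scores,
and platform error profiles.

All randomness derives from one integer seed; every stage draws from an
independent generator keyed by (seed, stage offset), so outputs are
byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import GenomeRecord, Interval, ReadRecord, reverse_complement
from .orfcall import OrfCall, OrfConfig, call_orfs, orf_subsequence, proteome
from .talign import local_align, search
from .recruit import CompositeDB
from .abundance import normalize_per_orf

__all__ = [
    "CommunityConfig",
    "Community",
    "random_coding_genome",
    "diverge_genome",
    "sample_reads",
    "make_standard_community",
    "recovery_harness",
    "write_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_STOPS = {"TAA", "TAG", "TGA"}
# sense codons of the bacterial code grouped by amino acid
_CODONS_BY_AA: dict[str, list[str]] = {}
from Bio.Data import CodonTable as _CT  # noqa: E402

for _codon, _aa in _CT.unambiguous_dna_by_id[11].forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
_AAS = sorted(_CODONS_BY_AA)


@dataclass(frozen=True)
class CommunityConfig:
    """Read-sampling configuration for a phage community.

    ``weights`` are relative abundances of the community genomes among
    non-background reads; ``background_fraction`` of reads are i.i.d.
    uniform nucleotides emulating unrelated virome content.
    """

    genomes: tuple[GenomeRecord, ...]
    weights: tuple[float, ...]
    n_reads: int
    read_len: int = 150
    error_rate: float = 0.01
    background_fraction: float = 0.5
    seed: int = 0
    metagenome_id: str = "sim"

    def __post_init__(self) -> None:
        if len(self.genomes) != len(self.weights):
            raise ValueError("one weight per genome required")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass(frozen=True)
class Community:
    """A focal community plus decoy relatives, with known abundances."""

    genomes: tuple[GenomeRecord, ...]
    weights: tuple[float, ...]
    decoys: tuple[GenomeRecord, ...]


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, offset])


def random_coding_genome(
    length: int, seed: int, genome_id: str = "phage", circular: bool = True,
    gene_len_codons: tuple[int, int] = (80, 300),
    spacer_len: tuple[int, int] = (20, 80),
) -> GenomeRecord:
    """A gene-dense random genome: alternating intergenic spacers and
    complete CDSs (ATG ... stop) on random strands, totalling ~``length``
    nt.  Gene content is random, so genomes from different seeds are
    unrelated."""
    rng = _rng(seed, 0)
    parts: list[str] = []
    total = 0
    while total < length:
        spacer = "".join(
            "ACGT"[b] for b in rng.integers(0, 4, rng.integers(*spacer_len))
        )
        n_codons = int(rng.integers(*gene_len_codons))
        aas = rng.choice(_AAS, n_codons)
        codons = ["ATG"] + [
            _CODONS_BY_AA[a][rng.integers(0, len(_CODONS_BY_AA[a]))] for a in aas
        ]
        cds = "".join(codons) + ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
        if rng.random() < 0.5:
            cds = reverse_complement(cds)
        parts += [spacer, cds]
        total += len(spacer) + len(cds)
    return GenomeRecord(genome_id, "".join(parts), circular=circular)


def _nonoverlapping(orfs: Sequence[OrfCall], genome_len: int) -> list[OrfCall]:
    """Longest-first greedy subset of ORFs with disjoint genome footprints;
    origin-spanning ORFs are skipped (their footprint wraps)."""
    kept: list[OrfCall] = []
    occupied: list[tuple[int, int]] = []
    for orf in sorted(orfs, key=lambda o: -o.span_nt()):
        iv = orf.interval
        if iv.end > genome_len:
            continue
        if any(iv.start <= e and s <= iv.end for s, e in occupied):
            continue
        kept.append(orf)
        occupied.append((iv.start, iv.end))
    return kept


def _mutate_coding(
    seq: list[str], orfs: Sequence[OrfCall], p: float, rng: np.random.Generator
) -> int:
    """Substitute amino acids inside ORFs at per-codon probability ``p``
    (start and stop codons untouched, no stops introduced); mutates
    ``seq`` in place and returns the number of nucleotide changes."""
    changed = 0
    for orf in orfs:
        g1, g2 = orf.interval.start, orf.interval.end
        cds = "".join(seq[g1 - 1 : g2])
        if orf.interval.strand == "-":
            cds = reverse_complement(cds)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        hit = np.nonzero(rng.random(len(codons) - 2) < p)[0] + 1  # internal only
        for ci in hit:
            old_aa = str(orf.protein[ci]) if ci < len(orf.protein) else None
            choices = [a for a in _AAS if a != old_aa]
            new_aa = choices[rng.integers(0, len(choices))]
            cods = _CODONS_BY_AA[new_aa]
            codons[ci] = cods[rng.integers(0, len(cods))]
        new_cds = "".join(codons)
        if orf.interval.strand == "-":
            new_cds = reverse_complement(new_cds)
        for k, base in enumerate(new_cds):
            if seq[g1 - 1 + k] != base:
                seq[g1 - 1 + k] = base
                changed += 1
    return changed


def _proteome_identity(
    genome: GenomeRecord, mutated: GenomeRecord, orfs: Sequence[OrfCall]
) -> float:
    """Length-weighted mean percent aa identity between original and
    mutated proteins, measured by local alignment."""
    num = den = 0.0
    from .orfcall import translate_orf

    for orf in orfs:
        new_prot = translate_orf(mutated, orf.interval)
        aln = local_align(orf.protein, new_prot)
        if aln is None:
            continue  # beyond alignable divergence; count as 0 over length
        num += aln.pct_identity * len(orf.protein)
        den += len(orf.protein)
    if den == 0:
        raise ValueError("no alignable proteins; divergence target unreachable")
    return num / den


def diverge_genome(
    genome: GenomeRecord,
    orfs: Sequence[OrfCall] | None,
    target_aa_identity: float,
    seed: int,
    genome_id: str | None = None,
    tol: float = 2.0,
    max_iter: int = 8,
) -> GenomeRecord:
    """Create a relative of ``genome`` whose proteome has a given mean
    amino-acid identity to the original.

    Substitution-only (no indels), codon-aware inside ORFs — start/stop
    codons preserved, no internal stops introduced — with intergenic
    regions mutated at the matching nucleotide rate, so ORF coordinates
    carry over unchanged.  The per-codon substitution probability is
    adjusted until the measured proteome identity is within ``tol``
    points of the target; failure to converge is an error.
    """
    if not 50.0 <= target_aa_identity <= 100.0:
        raise ValueError("target identity must be in [50, 100]")
    new_id = genome_id or f"{genome.id}_div{target_aa_identity:g}"
    if target_aa_identity == 100.0:
        return replace(genome, id=new_id)
    if orfs is None:
        orfs = call_orfs(genome)
    kept = _nonoverlapping(orfs, len(genome.seq))
    coding = {
        pos
        for o in kept
        for pos in range(o.interval.start - 1, o.interval.end)
    }
    p = 1.0 - target_aa_identity / 100.0
    for it in range(max_iter):
        rng = _rng(seed, 10 + it)
        seq = list(genome.seq)
        changed = _mutate_coding(seq, kept, p, rng)
        # intergenic positions drift at the realised coding nucleotide rate
        nt_rate = changed / max(len(coding), 1)
        intergenic = [i for i in range(len(seq)) if i not in coding]
        mask = rng.random(len(intergenic)) < nt_rate
        for i, flip in zip(intergenic, mask):
            if flip:
                alt = [b for b in "ACGT" if b != seq[i]]
                seq[i] = alt[rng.integers(0, 3)]
        mutated = GenomeRecord(new_id, "".join(seq), genome.circular)
        ident = _proteome_identity(genome, mutated, kept)
        if abs(ident - target_aa_identity) <= tol:
            return mutated
        # proportional correction on the divergence scale
        observed_div = max(100.0 - ident, 1e-3)
        p *= (100.0 - target_aa_identity) / observed_div
        p = min(max(p, 1e-4), 0.95)
    raise ValueError(
        f"could not reach {target_aa_identity}% identity within {max_iter} rounds"
    )


def sample_reads(cfg: CommunityConfig) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw shotgun reads from a weighted community plus random background.

    Returns the reads and a truth table (read_id, origin, position, strand)
    where position is the 1-based forward-strand start on the origin genome
    and origin is "background" for non-community reads.  Deterministic
    given the config seed.
    """
    for g in cfg.genomes:
        if cfg.read_len > len(g.seq):
            raise ValueError(
                f"read_len {cfg.read_len} exceeds genome {g.id} ({len(g.seq)} nt)"
            )
    rng = _rng(cfg.seed, 1)
    reads: list[ReadRecord] = []
    truth_rows = []
    weights = np.asarray(cfg.weights, dtype=float)
    for i in range(cfg.n_reads):
        rid = f"read{i:06d}"
        if rng.random() < cfg.background_fraction or len(cfg.genomes) == 0:
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, cfg.read_len))
            reads.append(ReadRecord(rid, seq, cfg.metagenome_id))
            truth_rows.append((rid, "background", 0, "."))
            continue
        gi = int(rng.choice(len(cfg.genomes), p=weights))
        g = cfg.genomes[gi]
        L = len(g.seq)
        if g.circular:
            pos = int(rng.integers(0, L))
            raw = (g.seq + g.seq)[pos : pos + cfg.read_len]
        else:
            pos = int(rng.integers(0, L - cfg.read_len + 1))
            raw = g.seq[pos : pos + cfg.read_len]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            raw = reverse_complement(raw)
        if cfg.error_rate > 0:
            arr = list(raw)
            errs = np.nonzero(rng.random(cfg.read_len) < cfg.error_rate)[0]
            for k in errs:
                alt = [b for b in "ACGT" if b != arr[k]]
                arr[k] = alt[rng.integers(0, 3)]
            raw = "".join(arr)
        reads.append(ReadRecord(rid, raw, cfg.metagenome_id))
        truth_rows.append((rid, g.id, pos + 1, strand))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "origin", "position", "strand"]
    )
    return reads, truth


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def make_standard_community(
    seed: int,
    n_phages: int = 5,
    genome_len: int = 50_000,
    member_identity: float = 85.0,
    decoy_identity: float = 60.0,
    n_decoys: int = 5,
) -> Community:
    """The standard benchmark community: ``n_phages`` relatives of one
    ancestor at ``member_identity`` % proteome identity with log-spaced
    weights 16:8:4:2:1, plus decoy relatives at ``decoy_identity`` %."""
    ancestor = random_coding_genome(genome_len, seed, "ancestor")
    orfs = call_orfs(ancestor)
    genomes = tuple(
        diverge_genome(ancestor, orfs, member_identity, seed + 1 + i, f"phage{i + 1}")
        for i in range(n_phages)
    )
    decoys = tuple(
        diverge_genome(ancestor, orfs, decoy_identity, seed + 101 + i, f"decoy{i + 1}")
        for i in range(n_decoys)
    )
    w = np.array([2.0 ** (n_phages - 1 - i) for i in range(n_phages)])
    return Community(genomes, tuple(w / w.sum()), decoys)


def recovery_harness(
    community: Community,
    n_reads: int = 20_000,
    read_len: int = 150,
    error_rate: float = 0.01,
    background_fraction: float = 0.5,
    cutoff: float = 1e-5,
    seed: int = 0,
    min_orf_aa: int = 60,
) -> tuple[float, pd.DataFrame]:
    """End-to-end abundance-recovery benchmark.

    Samples reads from the community, runs competitive recruitment with
    each community genome as the focal phage against the composite
    database of all community proteomes plus decoys, normalizes recruited
    counts per ORF per gigabase, and returns the Spearman rank correlation
    between the true weights and the normalized abundances (plus the
    per-phage table).

    Because competitive assignment depends only on each read's best hit in
    the shared composite database, the per-focal runs are computed from a
    single search pass; the result is identical to looping the two-stage
    pipeline over focal phages.
    """
    if len(community.genomes) < 3:
        raise ValueError("need at least 3 community phages")
    if len(set(community.weights)) == 1:
        raise ValueError("rank correlation undefined for all-equal weights")
    cfg = CommunityConfig(
        genomes=community.genomes,
        weights=community.weights,
        n_reads=n_reads,
        read_len=read_len,
        error_rate=error_rate,
        background_fraction=background_fraction,
        seed=seed,
    )
    reads, _truth = sample_reads(cfg)
    proteomes = {}
    n_orfs: dict[str, int] = {}
    for g in community.genomes:
        orfs = [o for o in call_orfs(g) if len(o.protein) >= min_orf_aa]
        proteomes[g.id] = proteome(orfs)
        n_orfs[g.id] = len(orfs)
    for d in community.decoys:
        orfs = [o for o in call_orfs(d) if len(o.protein) >= min_orf_aa]
        proteomes[d.id] = proteome(orfs)
    db = CompositeDB.from_proteomes(community.genomes[0].id, proteomes)
    best = search(reads, db, cutoff=cutoff, best_only=True)
    counts = {g.id: 0 for g in community.genomes}
    for hit in best:
        phage = db.phage_of[hit.subject_id]
        if phage in counts:
            counts[phage] += 1
    db_gb = n_reads * read_len / 1e9
    rows = []
    for g, w in zip(community.genomes, community.weights):
        rows.append(
            {
                "phage_id": g.id,
                "true_weight": w,
                "n_hits": counts[g.id],
                "n_orfs": n_orfs[g.id],
                "normalized": normalize_per_orf(counts[g.id], n_orfs[g.id], db_gb),
            }
        )
    table = pd.DataFrame(rows)
    rho = float(
        stats.spearmanr(table["true_weight"], table["normalized"]).statistic
    )
    return rho, table
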