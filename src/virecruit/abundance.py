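"""Normalized recruitment abundance and cross-metagenome ORF coverage.

Raw recruited-read counts are not comparable across phages or metagenomes:
a longer genome recruits more reads, and a larger metagenome yields more
hits.  Two normalizers are provided:

* per-ORF (default):      N = n_hits / (n_orfs x db_gb)
* per-genome-length:      N = n_hits / (genome_len_kb x db_gb)

where db_gb is the metagenome size in gigabases (1e9 bases of read
sequence, not file size; file-size accounting can be emulated by passing
an externally measured value).  The normalizer used is stamped into every
output row so tables from the two conventions cannot be silently mixed.

Coverage summaries count, per focal ORF, how many metagenomes of each
habitat class (e.g. freshwater vs marine) recruited at least one read
overlapping the ORF, and report how many ORFs clear >=1, >=2 and >=k
metagenomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .seqio import Interval, intervals_overlap
from .orfcall import OrfCall

__all__ = [
    "AbundanceRow",
    "normalize_per_orf",
    "normalize_per_length",
    "abundance_table",
    "rank_phages",
    "coverage_summary",
    "coverage_table",
]

ABUNDANCE_COLUMNS = [
    "phage_id",
    "metagenome_id",
    "n_hits",
    "normalizer",
    "n_orfs",
    "genome_len_kb",
    "db_size_gb",
    "normalized",
]


@dataclass(frozen=True)
class AbundanceRow:
    phage_id: str
    metagenome_id: str
    n_hits: int
    normalizer: str  # "per_orf" | "per_length"
    db_size_gb: float
    normalized: float
    n_orfs: int | None = None
    genome_len_kb: float | None = None


def normalize_per_orf(n_hits: int, n_orfs: int, db_gb: float) -> float:
    """Recruited hits per predicted ORF per gigabase of metagenome."""
    if n_orfs < 1:
        raise ValueError("n_orfs must be >= 1")
    if db_gb <= 0:
        raise ValueError("metagenome size must be positive")
    if n_hits < 0:
        raise ValueError("hit count cannot be negative")
    return n_hits / (n_orfs * db_gb)


def normalize_per_length(n_hits: int, genome_len_kb: float, db_gb: float) -> float:
    """Recruited hits per kilobase of phage genome per gigabase of
    metagenome."""
    if genome_len_kb <= 0:
        raise ValueError("genome length must be positive")
    if db_gb <= 0:
        raise ValueError("metagenome size must be positive")
    if n_hits < 0:
        raise ValueError("hit count cannot be negative")
    return n_hits / (genome_len_kb * db_gb)


def abundance_table(
    counts: Mapping[tuple[str, str], int],
    db_gb: Mapping[str, float],
    n_orfs: Mapping[str, int] | None = None,
    genome_len_kb: Mapping[str, float] | None = None,
    normalizer: str = "per_orf",
) -> pd.DataFrame:
    """Build an abundance table from (phage, metagenome) -> hit counts.

    Exactly one of ``n_orfs`` / ``genome_len_kb`` is consulted, depending
    on ``normalizer``.
    """
    if normalizer == "per_orf":
        if n_orfs is None:
            raise ValueError("per_orf normalizer requires n_orfs")
    elif normalizer == "per_length":
        if genome_len_kb is None:
            raise ValueError("per_length normalizer requires genome_len_kb")
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    rows = []
    for (phage, metag), n in sorted(counts.items()):
        gb = db_gb[metag]
        if normalizer == "per_orf":
            norm = normalize_per_orf(n, n_orfs[phage], gb)
        else:
            norm = normalize_per_length(n, genome_len_kb[phage], gb)
        rows.append(
            {
                "phage_id": phage,
                "metagenome_id": metag,
                "n_hits": n,
                "normalizer": normalizer,
                "n_orfs": n_orfs.get(phage) if n_orfs else None,
                "genome_len_kb": genome_len_kb.get(phage) if genome_len_kb else None,
                "db_size_gb": gb,
                "normalized": norm,
            }
        )
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


def rank_phages(rows: pd.DataFrame) -> pd.DataFrame:
    """Rank phages within one metagenome by normalized abundance
    (descending; ties by phage id ascending).

    All rows must share one metagenome and one normalizer; the output
    carries a 1-based ``rank`` column and is invariant under input row
    permutation.
    """
    if rows.empty:
        out = rows.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    if rows["metagenome_id"].nunique() > 1:
        raise ValueError("rank_phages expects rows from a single metagenome")
    if rows["normalizer"].nunique() > 1:
        raise ValueError("refusing to rank across mixed normalizers")
    out = rows.sort_values(
        ["normalized", "phage_id"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out


def coverage_summary(
    recruitment: pd.DataFrame,
    orfs: Sequence[OrfCall],
    habitat_of: Mapping[str, str],
    k: int = 5,
) -> dict:
    """Per-habitat ORF coverage counts from a recruitment table.

    ``recruitment`` needs columns metagenome_id, genome_start, genome_end.
    For each ORF and habitat class, the number of distinct metagenomes
    with >= 1 recruited read overlapping the ORF is counted; the summary
    reports how many ORFs reach >= 1, >= 2 ("multiple") and >= k
    ("extensive") metagenomes per habitat.
    """
    unknown = set(recruitment["metagenome_id"]) - set(habitat_of)
    if unknown:
        raise ValueError(f"metagenomes without habitat label: {sorted(unknown)}")
    habitats = sorted(set(habitat_of.values()))
    per_orf: dict[int, dict[str, set[str]]] = {
        o.index: {h: set() for h in habitats} for o in orfs
    }
    for row in recruitment.itertuples(index=False):
        iv = Interval(int(row.genome_start), int(row.genome_end))
        hab = habitat_of[row.metagenome_id]
        for o in orfs:
            if intervals_overlap(iv, Interval(o.interval.start, o.interval.end)):
                per_orf[o.index][hab].add(row.metagenome_id)
    summary: dict = {"per_orf": per_orf, "thresholds": {}}
    for h in habitats:
        counts = [len(per_orf[o.index][h]) for o in orfs]
        summary["thresholds"][h] = {
            "ge1": sum(c >= 1 for c in counts),
            "ge2": sum(c >= 2 for c in counts),
            f"ge{k}": sum(c >= k for c in counts),
        }
    return summary


def coverage_table(summary: dict) -> pd.DataFrame:
    """Flatten a coverage summary into orf_index x habitat counts."""
    per_orf = summary["per_orf"]
    habitats = sorted(next(iter(per_orf.values())).keys()) if per_orf else []
    rows = [
        {"orf_index": idx, **{f"{h}_count": len(per_orf[idx][h]) for h in habitats}}
        for idx in sorted(per_orf)
    ]
    return pd.DataFrame(rows)
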