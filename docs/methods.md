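# Methods

## Overview

`virecruit` measures the prevalence of sequences similar to a focal phage
in viral metagenomes by two-stage competitive fragment recruitment, and
packages the annotation steps the analysis depends on (ORF prediction with
a two-caller consensus, a terminator screen) together with a synthetic
community generator that makes the whole pipeline testable against known
ground truth.

## Coordinate conventions

All genomic coordinates are 1-based and fully inclusive. The canonical
interval form enforces start ≤ end with an explicit strand flag; published
annotation tables encode the minus strand inconsistently (sometimes as
start > end, sometimes via a strand column), so readers normalize on
input. For circular genomes, features spanning the origin are reported
once with *unwrapped* coordinates (end may exceed the genome length);
physical positions are recovered modulo the genome length. Interval length
is |end − start| + 1.

The "gigabase" used in abundance normalization is 10⁹ bases of read
sequence in the metagenome, not a file size: base count is reproducible
and independent of compression and format. An externally measured size
(e.g. a published database-size table) can be passed instead wherever a
`db_gb` value is accepted.

## ORF calling and consensus

The built-in caller reports every maximal start-to-stop frame on both
strands with nucleotide span strictly greater than `min_len_nt`
(default 100), using genetic code 11 and start codons {ATG, GTG, TTG}
(alternative initiators are rendered M). For circular genomes the scan
runs over the sequence virtually extended across the origin by one full
copy, and an ORF is recorded only after its preceding in-frame stop has
been seen; duplicates are removed by stop-codon anchor. This makes the
call set invariant under rotation of the linearized genome, which the test
suite asserts.

Two call sets (the built-in caller's, or external callers' imported via
GFF3) are merged by treating (stop-codon position, strand) as the locus
identity — gene finders disagree mostly on start choice — and keeping the
longer call at loci present in both inputs; loci seen by one caller are
kept as-is. The combiner is idempotent and commutative.

## Terminator screen

Candidate terminators are inverted repeats forming a stem-loop (stem 4–20
pairs from {G:C, A:T, G:U}, loop 3–10 nt) followed within 5 nt by ≥ 4 T
residues on the coding strand. The energy model is a transparent pair sum
(G:C −3.0, A:T −2.0, G:U −1.0 kcal/mol) plus a loop penalty of
4.0 + 0.3·(loop − 3) kcal; it is *not* a nearest-neighbor thermodynamic
calculation, and its purpose is that every reported energy is exactly
reproducible from the stated table. Calls require energy ≤ −16 kcal/mol
(the conventional screening threshold for this class of tool).
Overlapping candidates are resolved greedily, lowest energy first, ties by
leftmost start then plus strand — which makes the call count monotone in
the threshold. Each call is annotated with the nearest same-strand
upstream ORF within 200 nt (distance = gap between ORF 3′ end and the
reported interval's 5′ end; published distance columns run roughly 2–140
nt, hence the default window). The poly-T requirement can be disabled.

## Translated search

Reads are translated in all six frames (code 11); stop codons split frame
peptides into segments that are searched independently, since a stop
terminates any alignment extension. Local alignment is affine-gap
Smith–Waterman with BLOSUM62 and gap open 11 / extend 1, delegated to
Biopython's PairwiseAligner; the X produced by ambiguous codons is forced
to the matrix minimum so N bases behave as guaranteed mismatches.
Significance follows Karlin–Altschul statistics, E = K·m·n·exp(−λS) with
the published gapped constants λ = 0.267, K = 0.041 (not re-estimated);
m is the frame-peptide length and n the total residue count of the
protein database (configurable). Searching translated reads against a
protein database is equivalent, under the same scoring and cutoff, to the
mirrored protein-versus-translated-nucleotide search by the symmetry of
local alignment, and streams over arbitrarily many reads.

The default *seeded* mode indexes the database by exact 4-mers, extends
each seeded diagonal ungapped with an X-drop of 12, and runs the full DP
only where some diagonal reaches a trigger score of 30; segments too short
for any alignment to reach the E-cutoff score (bounded by the maximum
matrix diagonal) are skipped outright. At the raw scores an E ≤ 10⁻⁵ hit
requires (≈ 90 for typical database sizes here), a qualifying alignment
without a seeded diagonal at 30 is practically impossible, and the test
suite asserts exact agreement between seeded and exhaustive modes on
random and planted pairs. Hits are ranked bitscore descending, E
ascending, subject id ascending — a total order, so repeated runs are
byte-identical.

## Competitive recruitment

Stage 1 keeps reads with any hit at E ≤ 10⁻⁵ against the focal proteome.
Stage 2 searches candidates against the composite database (focal plus
decoy proteomes) and recruits a read iff its top-ranked hit belongs to the
focal phage. A true deterministic best hit replaces the common
"first target only" shortcut, whose result depends on database order.
Score ties between a focal and a decoy subject fall to the subject-id
tiebreak; focal ORF ids are kept bare while decoy subjects are namespaced
`phage|orf`, so exact ties resolve toward the focal phage — reads tied
between two focal proteins are likewise recruited, taking the interval
from the deterministic top hit. Both stages share the 10⁻⁵ cutoff by
default but are independently configurable. The percent identity reported
for a recruited read comes from the stage-2 alignment, the one that
justified recruitment.

The matched subject span [a1, a2] on an ORF at [g1, g2] maps to genome
nucleotides [g1 + 3(a1−1), g1 + 3a2 − 1] on the plus strand and
mirror-image from g2 downward on the minus strand, so every recruited
interval lies inside its ORF and recruited ⊆ candidates ⊆ reads holds by
construction; adding decoys can only shrink the recruited set.

## Abundance and coverage

Two normalizers are implemented because both conventions are in use:
per-ORF (N = hits / (ORF count × Gb), the default) and per-genome-length
(N = hits / (genome kb × Gb)). Every output row is stamped with the
normalizer used, and ranking refuses to mix them. Phages are ranked within
a metagenome by N descending, ties by phage id — invariant under row
permutation and positive rescaling. Coverage summaries count, per ORF and
habitat class, distinct metagenomes with ≥ 1 recruited read overlapping
the ORF, reporting how many ORFs reach ≥ 1, ≥ 2 ("multiple") and ≥ k
metagenomes; "extensively mapped" has no standard definition, so k is an
exposed parameter defaulting to 5.

## Synthetic communities

The generator emulates what the analysis assumes about a virome: related
genomes at known abundances, controlled divergence, read errors, and
non-homologous background.

* `random_coding_genome` builds gene-dense circular genomes (genes of
  80–300 codons on random strands separated by 20–80 nt spacers), roughly
  matching the coding density of phage genomes.
* `diverge_genome` creates relatives at a target mean proteome identity by
  codon-aware substitutions inside a maximal non-overlapping ORF subset
  (start/stop codons preserved, no internal stops introduced, no indels),
  with intergenic sequence mutated at the realized coding nucleotide rate.
  The per-codon substitution probability is iteratively adjusted until the
  identity measured by the package's own aligner is within ±2 points of
  target. Substitution-only divergence keeps coordinates stable, so
  recruitment positions remain comparable to truth; it does not model
  indels, rearrangement or gene gain/loss, so passing tests say nothing
  about synteny-sensitive analyses.
* `sample_reads` draws fixed-length reads (default 150 nt) from genomes
  proportional to weights (uniform positions, circular wrap, random
  strand), applies per-base substitution errors (default 1%), and mixes in
  i.i.d. uniform background reads (default fraction 0.5, emulating the
  unrelated majority of a virome). A truth table records every read's
  origin. No quality scores, platform error profiles or paired ends.
* `make_standard_community` is the benchmark condition: five ~50 kb
  relatives of one ancestor at 85% proteome identity with weights
  16:8:4:2:1, plus five decoy relatives at 60% identity.

All generators derive their randomness from one integer seed via fixed
stage offsets; outputs are byte-identical across runs.

`recovery_harness` runs recruitment with each community genome as focal
and reports the Spearman correlation between true weights and per-ORF
normalized recruited counts. Because a read's competitive assignment
depends only on its best hit in the shared composite database, and a read
whose best hit is phage P always passes P's stage-1 screen (the E-value
against the smaller focal database is smaller still), the per-focal runs
are computed from a single search pass — identical results, one fifth the
work. The harness restricts proteomes to ORFs ≥ 60 aa to keep spurious
mini-ORFs from inflating ORF counts.

## Problem sizes and runtime

The shipped benchmark uses 5 × 50 kb genomes, 2 × 10⁴ reads and a
composite database of ~2,300 proteins (~280k residues); it completes in
about 2.5 minutes on one CPU, and the full test suite in about 3 minutes.
The same code path scales to real metagenomes by streaming reads; the
composite decoy set stands in for a RefSeq-scale phage protein database,
which changes only the E-value search space n and the decoy diversity.

## Known limitations

* Karlin–Altschul constants are fixed; no composition-based score
  adjustment or multi-HSP sum statistics.
* The terminator energy model is deliberately simplified; its calls should
  not be compared against thermodynamic predictors.
* Seeded search is exact only in the regime where significant hits carry
  seeded diagonals — true at default cutoffs, not for permissive cutoffs
  (use `mode="exhaustive"` there).
* The simulator's background is uniform random sequence; real viromes
  contain low-identity homologs that would populate the E-value tail more
  densely than the null calibration suggests.
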