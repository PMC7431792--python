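"""Annotate a phage genome: ORF calling, two-caller consensus, and the
rho-independent terminator screen.

Builds a synthetic gene-dense circular genome, predicts its ORFs, shows the
longer-of-two consensus rule on a second call set, and screens for
terminators at the -16 kcal/mol threshold.
"""

from virecruit import OrfConfig, call_orfs, consensus_longer, find_terminators
from virecruit.simdata import random_coding_genome

genome = random_coding_genome(20_000, seed=42, genome_id="demo_phage")
print(f"genome {genome.id}: {len(genome.seq):,} bp, GC {genome.gc:.1f}%")

orfs = call_orfs(genome, OrfConfig(min_len_nt=100))
print(f"{len(orfs)} ORFs with span > 100 nt (both strands)")
for orf in orfs[:5]:
    iv = orf.interval
    print(f"  {orf.id:>6}  {iv.start:>6}..{iv.end:<6} {iv.strand}  {len(orf.protein)} aa")

# a second caller that trims starts: the consensus keeps the longer call
trimmed = [o for o in call_orfs(genome, OrfConfig(min_len_nt=200))]
merged = consensus_longer(orfs, trimmed)
print(f"consensus of the two call sets: {len(merged)} ORFs "
      "(longer call kept at each shared stop)")

terms = find_terminators(genome, orfs)
print(f"{len(terms)} terminator candidates at energy <= -16 kcal/mol")
for t in terms:
    print(f"  {t.interval.start}..{t.interval.end} {t.interval.strand} "
          f"{t.energy_kcal:.1f} kcal, upstream ORF {t.upstream_orf} "
          f"({t.distance_nt} nt away)" if t.upstream_orf else
          f"  {t.interval.start}..{t.interval.end} {t.interval.strand} "
          f"{t.energy_kcal:.1f} kcal")
# Each line is a stem-loop whose pair-sum energy clears the threshold and
# that is followed by a poly-T tract on its coding strand.
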